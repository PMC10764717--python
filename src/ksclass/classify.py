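"""Score-space classification of ketosynthase (KS) domains.

Every KS domain is scored against three reference profiles — animal
type I FAS, animal PKS and mitochondrial type II FAS ("FASII") — and
classified from that coordinate alone:

1. sequences whose best score misses the hit gate are NON_KS;
2. a FASII score above both type I scores marks the mitochondrial
   type II system (MITO_FASII);
3. a PKS score strictly above the FAS score (the y = x rule) marks PKS;
4. FAS-side sequences with FAS score inside [band_low, band_high) fall
   in the bridging band of FAS-like PKSs (AFPK);
5. FAS-side sequences at or above band_high are canonical TYPE_I_FAS;
6. FAS-side sequences below the band grade into the PKS continuum and
   default to PKS.

Band anchors from the source data: molluscs 400-600 bits, arthropods
200-500 bits against the FAS profile; hit gate 180 bits. These absolute
values presume full-length (~420-state) profiles; for smaller models
use :meth:`KSRuleClassifier.fit` to calibrate the gate and band from a
labeled training split.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .errors import EmptyInputError, ParameterError
from .phmm import ProfileHMM, forward_bitscore


class ClassLabel(str, enum.Enum):
    """The five score-space classes."""

    TYPE_I_FAS = "TYPE_I_FAS"
    AFPK = "AFPK"
    PKS = "PKS"
    MITO_FASII = "MITO_FASII"
    NON_KS = "NON_KS"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class ScoreTriple:
    """Bit scores of one sequence against the FAS / PKS / FASII profiles.

    Missing alignments are encoded as 0.0 (negative raw scores are
    clamped), so all components are finite and non-negative.
    """

    fas_bits: float
    pks_bits: float
    fasii_bits: float

    def __post_init__(self):
        for v in (self.fas_bits, self.pks_bits, self.fasii_bits):
            if not np.isfinite(v):
                raise ParameterError("score triple components must be finite")
            if v < 0:
                raise ParameterError(
                    "score triple components must be >= 0 (clamp no-alignment to 0.0)"
                )

    def as_array(self) -> np.ndarray:
        return np.array([self.fas_bits, self.pks_bits, self.fasii_bits])


PRESETS = {"mollusc": (400.0, 600.0), "arthropod": (200.0, 500.0)}


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds of the rule cascade (bits)."""

    hit_threshold: float = 180.0
    band_low: float = 400.0
    band_high: float = 600.0

    def __post_init__(self):
        if self.hit_threshold <= 0:
            raise ParameterError("hit_threshold must be positive")
        if not 0 < self.band_low < self.band_high:
            raise ParameterError("need 0 < band_low < band_high")

    @classmethod
    def from_preset(cls, preset: str, hit_threshold: float = 180.0) -> "ClassifierConfig":
        if preset not in PRESETS:
            raise ParameterError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
        low, high = PRESETS[preset]
        return cls(hit_threshold=hit_threshold, band_low=low, band_high=high)


def score_triple(seq, fas_hmm: ProfileHMM, pks_hmm: ProfileHMM, fasii_hmm: ProfileHMM) -> ScoreTriple:
    """Glocal forward bit scores against the three reference profiles,
    clamped at 0.0 (the no-alignment encoding)."""
    return ScoreTriple(
        fas_bits=max(0.0, forward_bitscore(fas_hmm, seq)),
        pks_bits=max(0.0, forward_bitscore(pks_hmm, seq)),
        fasii_bits=max(0.0, forward_bitscore(fasii_hmm, seq)),
    )


def pks_side(fas_bits: float, pks_bits: float) -> bool:
    """The y = x rule: strictly above the line (pks > fas) is PKS-side;
    ties fall on the FAS/AFPK side."""
    if not (np.isfinite(fas_bits) and np.isfinite(pks_bits)):
        raise ParameterError("pks_side requires finite scores")
    return pks_bits > fas_bits


def classify_ks(triple: ScoreTriple, config: ClassifierConfig) -> ClassLabel:
    """Apply the decision cascade to one score triple."""
    fas, pks, fasii = triple.fas_bits, triple.pks_bits, triple.fasii_bits
    if max(fas, pks, fasii) < config.hit_threshold:
        return ClassLabel.NON_KS
    if fasii > max(fas, pks):
        return ClassLabel.MITO_FASII
    if pks_side(fas, pks):
        return ClassLabel.PKS
    if config.band_low <= fas < config.band_high:
        return ClassLabel.AFPK
    if fas >= config.band_high:
        return ClassLabel.TYPE_I_FAS
    return ClassLabel.PKS  # FAS-side below the band: continuum tail


def score_panel(seqs, hmms) -> pd.DataFrame:
    """Score every sequence against every profile (glocal, clamped at 0).

    Returns a DataFrame indexed by sequence id with one column per
    profile name, in input order.
    """
    seqs = list(seqs)
    hmms = list(hmms)
    if not seqs or not hmms:
        raise EmptyInputError("score_panel needs at least one sequence and one profile")
    names = [h.name for h in hmms]
    if len(set(names)) != len(names):
        raise ParameterError("profile names must be unique")
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise ParameterError("sequence ids must be unique")
    values = np.empty((len(seqs), len(hmms)))
    for j, h in enumerate(hmms):
        for i, s in enumerate(seqs):
            values[i, j] = max(0.0, forward_bitscore(h, s))
    return pd.DataFrame(values, index=pd.Index(ids, name="seq_id"), columns=names)


def dotplot_table(triples, config: ClassifierConfig | None = None) -> pd.DataFrame:
    """Rank sequences by FAS bit score (the dot-plot ordering).

    ``triples`` is an iterable of ``(seq_id, ScoreTriple)``. Rows are
    sorted by ``fas_bits`` descending, ties by id ascending; columns are
    rank, seq_id, fas_bits, pks_bits, fasii_bits, label.
    """
    config = config or ClassifierConfig()
    rows = sorted(triples, key=lambda p: (-p[1].fas_bits, p[0]))
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(rows) + 1),
            "seq_id": [sid for sid, _ in rows],
            "fas_bits": [t.fas_bits for _, t in rows],
            "pks_bits": [t.pks_bits for _, t in rows],
            "fasii_bits": [t.fasii_bits for _, t in rows],
            "label": [classify_ks(t, config).value for _, t in rows],
        }
    )


def _cascade_vectorized(X: np.ndarray, hit: float, low: float, high: float) -> np.ndarray:
    fas, pks, fasii = X[:, 0], X[:, 1], X[:, 2]
    best = X.max(axis=1)
    return np.select(
        [
            best < hit,
            fasii > np.maximum(fas, pks),
            pks > fas,
            (low <= fas) & (fas < high),
            fas >= high,
        ],
        [
            ClassLabel.NON_KS.value,
            ClassLabel.MITO_FASII.value,
            ClassLabel.PKS.value,
            ClassLabel.AFPK.value,
            ClassLabel.TYPE_I_FAS.value,
        ],
        default=ClassLabel.PKS.value,
    )


class KSRuleClassifier(ClassifierMixin, BaseEstimator):
    """Rule-cascade classifier over (fas, pks, fasii) bit-score triples.

    A scikit-learn estimator whose decision function is the fixed
    cascade of :func:`classify_ks`. ``fit`` either adopts the configured
    thresholds verbatim (``y=None``) or calibrates the hit gate and the
    AFPK band from labeled training triples, which is required whenever
    the profiles are not full-length (absolute bit values scale with
    model length).

    Parameters
    ----------
    hit_threshold, band_low, band_high:
        Cascade thresholds in bits; defaults are the full-length-profile
        anchors (gate 180, mollusc band 400-600).
    preset:
        Optional band preset name ("mollusc" or "arthropod") overriding
        band_low/band_high.

    Attributes
    ----------
    hit_threshold_, band_low_, band_high_ : float
        Thresholds in effect after fitting.
    classes_ : ndarray of str
    """

    def __init__(self, hit_threshold: float = 180.0, band_low: float = 400.0,
                 band_high: float = 600.0, preset: str | None = None):
        self.hit_threshold = hit_threshold
        self.band_low = band_low
        self.band_high = band_high
        self.preset = preset

    def _configured(self) -> ClassifierConfig:
        if self.preset is not None:
            return ClassifierConfig.from_preset(self.preset, hit_threshold=self.hit_threshold)
        return ClassifierConfig(self.hit_threshold, self.band_low, self.band_high)

    def fit(self, X, y=None):
        cfg = self._configured()
        hit, low, high = cfg.hit_threshold, cfg.band_low, cfg.band_high
        if y is None:
            X = check_array(X, ensure_min_features=3)
        else:
            X, y = check_X_y(X, y, dtype=float)
            if X.shape[1] != 3:
                raise ParameterError("expected (n, 3) score triples")
            y = np.asarray(y, dtype=object)
            ks_labels = {
                ClassLabel.TYPE_I_FAS.value,
                ClassLabel.AFPK.value,
                ClassLabel.PKS.value,
                ClassLabel.MITO_FASII.value,
            }
            ks_mask = np.isin(y, list(ks_labels))
            fas = X[:, 0]
            if ks_mask.any():
                # Gate: half the 1st percentile of the best score among
                # known KS sequences — scale-free and conservative.
                hit = max(1.0, 0.5 * float(np.percentile(X[ks_mask].max(axis=1), 1)))
            afpk, fasc, pksc = (y == ClassLabel.AFPK.value), (y == ClassLabel.TYPE_I_FAS.value), (y == ClassLabel.PKS.value)
            if afpk.any() and fasc.any():
                high = 0.5 * (fas[afpk].mean() + fas[fasc].mean())
            if afpk.any():
                pks_fas95 = float(np.percentile(fas[pksc], 95)) if pksc.any() else 0.0
                low = max(1.0, 0.5 * (float(np.percentile(fas[afpk], 5)) + pks_fas95))
            if low >= high:
                low = 0.5 * high
        self.hit_threshold_ = float(hit)
        self.band_low_ = float(low)
        self.band_high_ = float(high)
        self.classes_ = np.array(sorted(l.value for l in ClassLabel))
        self.n_features_in_ = 3
        return self

    def predict(self, X):
        check_is_fitted(self, "hit_threshold_")
        X = check_array(X, dtype=float)
        if X.shape[1] != 3:
            raise ParameterError("expected (n, 3) score triples")
        return _cascade_vectorized(X, self.hit_threshold_, self.band_low_, self.band_high_)

    def config_(self) -> ClassifierConfig:
        check_is_fitted(self, "hit_threshold_")
        return ClassifierConfig(self.hit_threshold_, self.band_low_, self.band_high_)
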