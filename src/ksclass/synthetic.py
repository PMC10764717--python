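"""Synthetic KS-like protein families for desk-scale experiments.

Each family is a profile HMM whose match columns concentrate a fixed
probability mass (``conservation``) on a per-column preferred residue,
with the remainder spread over the other residues in proportion to the
background. "Intermediate" families are convex combinations of two
parent models' emission and transition probabilities, controlled by a
single mixing fraction λ — a minimal, tunable stand-in for the observed
score continuum bridging animal FAS and PKS enzymes. Sequences sampled
from the λ-grid reproduce the bridging phenomenology: their mean bit
score against parent A decreases strictly in λ while the score against
parent B increases.

The generator makes no attempt at biological realism beyond this score
geometry: columns are independent, there is no site-rate heterogeneity,
no phylogenetic correlation between sequences, and indels are geometric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, UnknownIdError
from .phmm import (
    N_AA,
    T_DD,
    T_DM,
    T_II,
    T_IM,
    T_MD,
    T_MI,
    T_MM,
    UNIFORM_BACKGROUND,
    ProfileHMM,
    sample_sequence,
)
from .seqio import AMINO_ACIDS, ProteinSequence


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of one synthetic family model.

    M defaults to 120 match states (desk scale); use 420 for a model the
    length of a real KS domain. ``conservation`` is the emission mass on
    each column's preferred residue and must exceed the background mass
    1/20, else the family is indistinguishable from noise.
    """

    name: str
    M: int = 120
    conservation: float = 0.7
    indel_rate: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.M < 1:
            raise ParameterError("M must be >= 1")
        if not (1.0 / N_AA) < self.conservation <= 1.0 - 1e-6:
            raise ParameterError("conservation must lie in (0.05, 1)")
        if not 0.0 <= self.indel_rate <= 0.2:
            raise ParameterError("indel_rate must lie in [0, 0.2]")


@dataclass(frozen=True)
class MixtureSpec:
    """A λ-interpolated intermediate between two named parent families."""

    parent_a: str
    parent_b: str
    lam: float
    name: str = ""

    def __post_init__(self):
        if not 0.0 <= self.lam <= 1.0:
            raise ParameterError("lambda must lie in [0, 1]")
        if not self.name:
            object.__setattr__(
                self, "name", f"{self.parent_a}x{self.parent_b}@{self.lam:g}"
            )


@dataclass
class LabeledDataset:
    """Sequences with per-sequence family labels and provenance."""

    sequences: list
    labels: list
    provenance: list  # (family_name, lambda, seed) per sequence

    def __post_init__(self):
        if not (len(self.sequences) == len(self.labels) == len(self.provenance)):
            raise ParameterError("dataset fields must have equal length")

    def subset(self, indices) -> "LabeledDataset":
        idx = list(indices)
        return LabeledDataset(
            [self.sequences[i] for i in idx],
            [self.labels[i] for i in idx],
            [self.provenance[i] for i in idx],
        )

    def split(self, train_fraction: float = 0.5, seed: int = 0):
        """Stratified train/test split, deterministic given seed."""
        rng = np.random.default_rng(seed)
        train_idx, test_idx = [], []
        labels = np.asarray(self.labels, dtype=object)
        for lab in sorted(set(self.labels)):
            pos = np.flatnonzero(labels == lab)
            pos = pos[rng.permutation(len(pos))]
            cut = int(round(train_fraction * len(pos)))
            train_idx.extend(pos[:cut])
            test_idx.extend(pos[cut:])
        return self.subset(sorted(train_idx)), self.subset(sorted(test_idx))


def make_family_hmm(spec: FamilySpec, background=None) -> ProfileHMM:
    """Build the profile HMM of one synthetic family.

    Per match column a preferred residue is drawn uniformly (seeded);
    it receives ``conservation`` emission mass and the rest is spread
    over the other residues proportional to background. Transitions are
    uniform across nodes with MI = MD = indel_rate / 2.
    """
    bg = UNIFORM_BACKGROUND.copy() if background is None else np.asarray(background, float)
    rng = np.random.default_rng(spec.seed)
    preferred = rng.integers(0, N_AA, size=spec.M)
    emissions = np.empty((spec.M, N_AA))
    for j, p in enumerate(preferred):
        rest = bg.copy()
        rest[p] = 0.0
        emissions[j] = (1.0 - spec.conservation) * rest / rest.sum()
        emissions[j, p] += spec.conservation
    half = spec.indel_rate / 2.0
    node = np.array([1.0 - spec.indel_rate, half, half, 0.60, 0.40, 0.60, 0.40])
    if spec.indel_rate == 0.0:
        # keep probabilities strictly positive for valid models
        node[[T_MI, T_MD]] = 1e-9
        node[T_MM] = 1.0 - 2e-9
    transitions = np.tile(node, (spec.M + 1, 1))
    return ProfileHMM(
        name=spec.name,
        match_emissions=emissions,
        insert_emissions=bg.copy(),
        transitions=transitions,
        background=bg.copy(),
    )


def interpolate_models(a: ProfileHMM, b: ProfileHMM, lam: float, name: str | None = None) -> ProfileHMM:
    """Convex combination of two equal-length models: (1-λ)·a + λ·b."""
    if a.M != b.M:
        raise ParameterError(f"model lengths differ: {a.M} vs {b.M}")
    if not 0.0 <= lam <= 1.0:
        raise ParameterError("lambda must lie in [0, 1]")

    def mix(x, y):
        z = (1.0 - lam) * x + lam * y
        return z / z.sum(axis=-1, keepdims=True)

    trans = (1.0 - lam) * a.transitions + lam * b.transitions
    for group in ((T_MM, T_MI, T_MD), (T_IM, T_II), (T_DM, T_DD)):
        idx = list(group)
        trans[:, idx] = trans[:, idx] / trans[:, idx].sum(axis=1, keepdims=True)
    return ProfileHMM(
        name=name or f"{a.name}+{b.name}@{lam:g}",
        match_emissions=mix(a.match_emissions, b.match_emissions),
        insert_emissions=mix(a.insert_emissions, b.insert_emissions),
        transitions=trans,
        background=mix(a.background, b.background),
    )


def mutate_sequence(seq: ProteinSequence, rate: float, rng) -> ProteinSequence:
    """Substitute each position independently with probability ``rate``
    by a uniform draw from the 19 other residues."""
    if not 0.0 <= rate <= 1.0:
        raise ParameterError("rate must lie in [0, 1]")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    residues = list(seq.residues)
    hits = rng.random(len(residues)) < rate
    for i in np.flatnonzero(hits):
        current = residues[i]
        alternatives = [a for a in AMINO_ACIDS if a != current]
        residues[i] = alternatives[rng.integers(0, len(alternatives))]
    return ProteinSequence(id=seq.id, residues="".join(residues), description=seq.description)


def build_models(families, mixtures):
    """Family + mixture models keyed by name; mixtures may reference
    only declared family names."""
    models = {}
    for spec in families:
        models[spec.name] = make_family_hmm(spec)
    for mix in mixtures:
        for parent in (mix.parent_a, mix.parent_b):
            if parent not in models:
                raise UnknownIdError(f"mixture references unknown family {parent!r}")
        models[mix.name] = interpolate_models(
            models[mix.parent_a], models[mix.parent_b], mix.lam, name=mix.name
        )
    return models


def generate_labeled_dataset(
    families,
    mixtures,
    n_per_class: int,
    noise_rate: float = 0.0,
    seed: int = 0,
) -> LabeledDataset:
    """Sample ``n_per_class`` sequences from every family and mixture
    model, apply substitution noise, and record labels + provenance.
    Fully deterministic given ``seed``."""
    if n_per_class < 1:
        raise ParameterError("n_per_class must be >= 1")
    models = build_models(families, mixtures)
    lam_of = {m.name: m.lam for m in mixtures}
    class_names = [f.name for f in families] + [m.name for m in mixtures]
    children = np.random.SeedSequence(seed).spawn(len(class_names))
    sequences, labels, provenance = [], [], []
    for name, child in zip(class_names, children):
        rng = np.random.default_rng(child)
        for j in range(n_per_class):
            s = sample_sequence(models[name], rng, seq_id=f"{name}|{j:04d}")
            if noise_rate > 0:
                s = mutate_sequence(s, noise_rate, rng)
            sequences.append(s)
            labels.append(name)
            provenance.append((name, lam_of.get(name), seed))
    return LabeledDataset(sequences, labels, provenance)


#: Default mixing fraction of the intermediate (AFPK-like) class in the
#: three-class benchmark. The bridging enzymes sit on the FAS side of
#: the y = x line with an intermediate FAS score (the 400-600-of-600+
#: band), which a FAS-weighted mixture reproduces; an equal mixture
#: would straddle the line instead.
DEFAULT_AFPK_LAMBDA = 0.35


def three_class_benchmark(
    n_per_class: int = 100,
    M: int = 120,
    conservation: float = 0.7,
    indel_rate: float = 0.02,
    noise_rate: float = 0.05,
    lambda_afpk: float = DEFAULT_AFPK_LAMBDA,
    seed: int = 0,
):
    """The standard synthetic study: FAS-like, AFPK-like and PKS-like
    classes plus the three scoring models (FAS, PKS and an unrelated
    FASII stand-in).

    Returns ``(dataset, models)`` where ``dataset`` labels are the class
    names ``TYPE_I_FAS`` / ``AFPK`` / ``PKS`` and ``models`` maps
    ``fas`` / ``pks`` / ``fasii`` to profiles.
    """
    rng = np.random.default_rng(seed)
    fam_seeds = rng.integers(0, 2**31 - 1, size=3)
    fas_spec = FamilySpec("TYPE_I_FAS", M=M, conservation=conservation,
                          indel_rate=indel_rate, seed=int(fam_seeds[0]))
    pks_spec = FamilySpec("PKS", M=M, conservation=conservation,
                          indel_rate=indel_rate, seed=int(fam_seeds[1]))
    fasii_spec = FamilySpec("MITO_FASII", M=M, conservation=conservation,
                            indel_rate=indel_rate, seed=int(fam_seeds[2]))
    mixture = MixtureSpec("TYPE_I_FAS", "PKS", lambda_afpk, name="AFPK")
    dataset = generate_labeled_dataset(
        [fas_spec, pks_spec], [mixture], n_per_class, noise_rate,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    models = build_models([fas_spec, pks_spec, fasii_spec], [])
    return dataset, {
        "fas": models["TYPE_I_FAS"],
        "pks": models["PKS"],
        "fasii": models["MITO_FASII"],
    }
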