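"""Profile hidden Markov models over protein sequences.

The model is a simplified Plan7-like architecture: M match states with
position-specific emissions, one shared insert-emission vector, and
per-node transition tuples (MM, MI, MD, IM, II, DM, DD) where node 0 is
the begin state and node M's match/delete transitions route to the end
state. Scores are log2 likelihood ratios against an i.i.d. background
null of the same length ("bit scores"). There is no multihit extension,
no bias-composition filter and no null-length correction, so absolute
values are not comparable to HMMER's — only relative scores matter for
the classification rules built on top.

Numerics: the forward recursion runs in emission-odds space (each
emission divided by its background probability, which makes the null
cancel exactly and lets ``X`` contribute zero bits) with per-position
max renormalization; the accumulated log2 scale is added back at the
end. The within-position delete chain is a first-order linear
recurrence solved in vectorized chunks. Local-mode Viterbi runs in
plain log2 space.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .errors import (
    EmptyInputError,
    EmptyModelError,
    ParameterError,
    ProfileParseError,
    SchemaVersionError,
    UnsupportedAlphabetError,
    ValidationError,
)
from .seqio import AMINO_ACIDS, GAP_CHARS, MultipleAlignment, ProteinSequence

AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
N_AA = 20

# Transition tuple layout per node.
T_MM, T_MI, T_MD, T_IM, T_II, T_DM, T_DD = range(7)
TRANSITION_NAMES = ("MM", "MI", "MD", "IM", "II", "DM", "DD")

#: Dirichlet-like transition priors blended with observed counts in
#: :func:`build_profile` (match: strongly favors staying on the match
#: track; insert/delete: moderate extension probability).
TRANSITION_PRIORS = np.array([0.90, 0.05, 0.05, 0.60, 0.40, 0.60, 0.40])

UNIFORM_BACKGROUND = np.full(N_AA, 1.0 / N_AA)

_PROFILE_SCHEMA_VERSION = 1


def _check_distribution(vec, name, tol=1e-8):
    vec = np.asarray(vec, dtype=float)
    if np.any(vec <= 0) or not np.all(np.isfinite(vec)):
        raise ValidationError(f"{name} must be strictly positive and finite")
    if abs(vec.sum() - 1.0) > tol:
        raise ValidationError(f"{name} does not sum to 1 (got {vec.sum():.12f})")
    return vec


@dataclass
class ProfileHMM:
    """A profile HMM with M match states.

    Attributes
    ----------
    name : str
    match_emissions : (M, 20) array of per-state emission probabilities.
    insert_emissions : (20,) array shared by all insert states.
    transitions : (M + 1, 7) array, rows indexed by node 0..M with columns
        (MM, MI, MD, IM, II, DM, DD); node 0 is the begin state and node M's
        MM/MD probabilities route to the end state.
    background : (20,) array, the null emission distribution.
    """

    name: str
    match_emissions: np.ndarray
    insert_emissions: np.ndarray
    transitions: np.ndarray
    background: np.ndarray

    def __post_init__(self):
        self.match_emissions = np.asarray(self.match_emissions, dtype=float)
        self.insert_emissions = np.asarray(self.insert_emissions, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        self.validate()

    @property
    def M(self) -> int:
        return self.match_emissions.shape[0]

    def validate(self) -> None:
        if self.match_emissions.ndim != 2 or self.match_emissions.shape[1] != N_AA:
            raise ValidationError("match_emissions must have shape (M, 20)")
        if self.M < 1:
            raise ValidationError("profile needs at least one match state")
        if self.insert_emissions.shape != (N_AA,):
            raise ValidationError("insert_emissions must have shape (20,)")
        if self.transitions.shape != (self.M + 1, 7):
            raise ValidationError(
                f"transitions must have shape ({self.M + 1}, 7), "
                f"got {self.transitions.shape}"
            )
        if self.background.shape != (N_AA,):
            raise ValidationError("background must have shape (20,)")
        for j in range(self.M):
            _check_distribution(self.match_emissions[j], f"match emission row {j}")
        _check_distribution(self.insert_emissions, "insert emissions")
        _check_distribution(self.background, "background")
        t = self.transitions
        if np.any(t <= 0) or not np.all(np.isfinite(t)):
            raise ValidationError("transitions must be strictly positive and finite")
        for cols, label in (((T_MM, T_MI, T_MD), "M"), ((T_IM, T_II), "I"), ((T_DM, T_DD), "D")):
            sums = t[:, list(cols)].sum(axis=1)
            if np.any(np.abs(sums - 1.0) > 1e-8):
                raise ValidationError(f"{label}-state transitions do not sum to 1")


def _normalize_rows(a, axis=-1):
    a = np.asarray(a, dtype=float)
    return a / a.sum(axis=axis, keepdims=True)


def build_profile(
    msa: MultipleAlignment,
    gap_threshold: float = 0.5,
    pseudocount_weight: float = 5.0,
    background="uniform",
    name: str = "profile",
) -> ProfileHMM:
    """Estimate a profile HMM from a seed alignment.

    Columns whose gap fraction is <= ``gap_threshold`` become match states.
    Match emissions are pseudocount-smoothed observed frequencies,
    ``(count + w * bg) / (n + w)``, where ``X`` residues contribute to no
    count. Transition probabilities blend observed state-path counts with
    the fixed priors in :data:`TRANSITION_PRIORS` at the same weight.
    Insert emissions equal the background.
    """
    if not 0.0 <= gap_threshold <= 1.0:
        raise ParameterError("gap_threshold must lie in [0, 1]")
    if pseudocount_weight <= 0:
        raise ParameterError("pseudocount_weight must be positive")
    bg = UNIFORM_BACKGROUND.copy() if isinstance(background, str) and background == "uniform" \
        else _check_distribution(background, "background")
    w = float(pseudocount_weight)

    n_rows, n_cols = msa.n_rows, msa.n_columns
    cols = [[row[c] for row in msa.rows] for c in range(n_cols)]
    gap_frac = [sum(ch in GAP_CHARS for ch in col) / n_rows for col in cols]
    match_cols = [c for c in range(n_cols) if gap_frac[c] <= gap_threshold]
    if not match_cols:
        raise EmptyModelError("no alignment column qualifies as a match state")
    M = len(match_cols)
    is_match = [False] * n_cols
    for c in match_cols:
        is_match[c] = True

    # Emission counts (X excluded).
    emit_counts = np.zeros((M, N_AA))
    for j, c in enumerate(match_cols):
        for ch in cols[c]:
            if ch in AA_INDEX:
                emit_counts[j, AA_INDEX[ch]] += 1
    match_emissions = (emit_counts + w * bg) / (
        emit_counts.sum(axis=1, keepdims=True) + w
    )

    # Transition counts from per-row state paths. Within a row, a match
    # column maps to M_k (residue) or D_k (gap); residues in insert
    # columns map to I_k for the current node k.
    trans_counts = np.zeros((M + 1, 7))
    _PAIR_COL = {
        ("M", "M"): T_MM, ("M", "D"): T_MD, ("I", "M"): T_IM,
        ("D", "M"): T_DM, ("D", "D"): T_DD,
    }
    for row in msa.rows:
        state, node = "M", 0  # begin behaves like node-0 match
        for c in range(n_cols):
            ch = row[c]
            if is_match[c]:
                nxt = "D" if ch in GAP_CHARS else "M"
                col = _PAIR_COL.get((state, nxt))
                if col is not None:  # I->D and D<-I are not in the topology
                    trans_counts[node, col] += 1
                node += 1
                state = nxt
            elif ch not in GAP_CHARS:
                if state == "M":
                    trans_counts[node, T_MI] += 1
                elif state == "I":
                    trans_counts[node, T_II] += 1
                state = "I"  # D->I occurrences contribute no count
        # exit to the end state from node M
        trans_counts[node, {"M": T_MM, "I": T_IM, "D": T_DM}[state]] += 1

    transitions = np.empty((M + 1, 7))
    for cols_group in ((T_MM, T_MI, T_MD), (T_IM, T_II), (T_DM, T_DD)):
        idx = list(cols_group)
        counts = trans_counts[:, idx]
        prior = TRANSITION_PRIORS[idx]
        blended = counts + w * prior
        transitions[:, idx] = blended / blended.sum(axis=1, keepdims=True)

    return ProfileHMM(
        name=name,
        match_emissions=match_emissions,
        insert_emissions=bg.copy(),
        transitions=transitions,
        background=bg.copy(),
    )


@dataclass(frozen=True)
class DomainHit:
    """A located domain window on a query protein (0-based, half-open)."""

    start: int
    end: int
    bits: float

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValidationError("DomainHit requires 0 <= start < end")
        if not math.isfinite(self.bits):
            raise ValidationError("DomainHit bits must be finite")


def _encode(seq) -> tuple[str, np.ndarray]:
    residues = seq.residues if isinstance(seq, ProteinSequence) else str(seq)
    if len(residues) == 0:
        raise EmptyInputError("cannot score an empty sequence")
    idx = np.fromiter((AA_INDEX.get(c, -1) for c in residues), dtype=np.int64)
    return residues, idx


def _linear_chain(b: np.ndarray, c: np.ndarray, chunk: int = 24) -> np.ndarray:
    """Solve d[k] = b[k] + c[k] * d[k-1] (d[-1] = 0), vectorized in chunks.

    Chunking bounds the cumulative products away from under/overflow;
    contributions routed through near-zero coefficients are negligible by
    construction and may be absorbed into the floor.
    """
    n = b.shape[0]
    d = np.empty(n)
    carry = 0.0
    cc = np.maximum(c, 1e-12)
    for s in range(0, n, chunk):
        e = min(s + chunk, n)
        q = np.cumprod(cc[s:e])
        inner = np.cumsum(b[s:e] / q)
        # d[s+j] = q[j]*carry + q[j]*sum_{m<=j} b[s+m]/q[m]
        d[s:e] = q * carry + q * inner
        carry = d[e - 1]
    return d


def forward_bitscore(hmm: ProfileHMM, seq, mode: str = "glocal") -> float:
    """Forward-algorithm bit score of ``seq`` under ``hmm``.

    Returns ``log2(P(seq | hmm, mode) / P(seq | null))`` where the
    forward probability sums over all state paths and the null emits
    each residue i.i.d. from the background. ``X`` residues emit their
    background probability under every state and contribute 0 bits.

    ``glocal`` traverses the whole model and emits the full sequence;
    ``local`` sums over all contiguous model/sequence fragments (unihit,
    unit entry/exit weights), with flanking residues emitted by the null.
    """
    if mode not in ("glocal", "local"):
        raise ParameterError(f"unknown scoring mode {mode!r}")
    _, idx = _encode(seq)
    M = hmm.M
    t = hmm.transitions
    ratio_match = hmm.match_emissions / hmm.background  # (M, 20)
    ratio_ins = hmm.insert_emissions / hmm.background  # (20,)
    ones_m = np.ones(M)

    if mode == "glocal":
        aM = np.zeros(M + 1)
        aM[0] = 1.0
        aI = np.zeros(M + 1)
        aD = np.zeros(M + 1)
        aD[1:] = _linear_chain(aM[:M] * t[:M, T_MD], t[:M, T_DD])
        log2_scale = 0.0
        for a in idx:
            rm = ratio_match[:, a] if a >= 0 else ones_m
            ri = ratio_ins[a] if a >= 0 else 1.0
            newM = np.zeros(M + 1)
            newM[1:] = rm * (
                aM[:M] * t[:M, T_MM] + aI[:M] * t[:M, T_IM] + aD[:M] * t[:M, T_DM]
            )
            newI = ri * (aM * t[:, T_MI] + aI * t[:, T_II])
            newD = np.zeros(M + 1)
            newD[1:] = _linear_chain(newM[:M] * t[:M, T_MD], t[:M, T_DD])
            s = max(newM.max(), newI.max(), newD.max())
            if s <= 0 or not math.isfinite(s):
                return -math.inf
            newM /= s
            newI /= s
            newD /= s
            log2_scale += math.log2(s)
            aM, aI, aD = newM, newI, newD
        p_end = (
            aM[M] * (t[M, T_MM] + t[M, T_MD])
            + aI[M] * t[M, T_IM]
            + aD[M] * (t[M, T_DM] + t[M, T_DD])
        )
        if p_end <= 0:
            return -math.inf
        return math.log2(p_end) + log2_scale

    # local: fragment alignments may start at any match state and end at
    # any match state; residues outside the fragment score 0 bits.
    aM = np.zeros(M + 1)
    aI = np.zeros(M + 1)
    aD = np.zeros(M + 1)
    log2_scale = 0.0
    total_log2 = -math.inf
    for a in idx:
        rm = ratio_match[:, a] if a >= 0 else ones_m
        ri = ratio_ins[a] if a >= 0 else 1.0
        # Fresh entry carries unit weight in unscaled units.
        entry = 2.0 ** (-log2_scale) if log2_scale > -1000.0 else math.inf
        if not math.isfinite(entry):
            entry = 0.0  # unreachable in practice; keeps the DP defined
        newM = np.zeros(M + 1)
        newM[1:] = rm * (
            aM[:M] * t[:M, T_MM] + aI[:M] * t[:M, T_IM] + aD[:M] * t[:M, T_DM] + entry
        )
        newI = ri * (aM * t[:, T_MI] + aI * t[:, T_II])
        newD = np.zeros(M + 1)
        newD[1:] = _linear_chain(newM[:M] * t[:M, T_MD], t[:M, T_DD])
        exit_mass = newM[1:].sum()
        if exit_mass > 0:
            total_log2 = np.logaddexp2(total_log2, math.log2(exit_mass) + log2_scale)
        s = max(newM.max(), newI.max(), newD.max())
        if s > 0:
            newM /= s
            newI /= s
            newD /= s
            log2_scale += math.log2(s)
        aM, aI, aD = newM, newI, newD
    return float(total_log2)


def _viterbi_local_matrices(hmm: ProfileHMM, idx: np.ndarray):
    """Log2-space local Viterbi DP matrices (vM, vI, vD), shape (L+1, M+1)."""
    M = hmm.M
    L = idx.shape[0]
    lt = np.log2(hmm.transitions)
    lrm_full = np.log2(hmm.match_emissions / hmm.background)  # (M, 20)
    lri_full = np.log2(hmm.insert_emissions / hmm.background)
    NEG = -np.inf
    vM = np.full((L + 1, M + 1), NEG)
    vI = np.full((L + 1, M + 1), NEG)
    vD = np.full((L + 1, M + 1), NEG)
    # Cumulative delete-extension costs for the within-row chain:
    # vD[i, k] = C[k-1] + max_{j<=k-1} (vM[i, j] + ltMD[j] - C[j]),
    # where C[k] = sum_{l<=k} ltDD[l].
    ltDD = lt[:, T_DD]
    C = np.concatenate(([0.0], np.cumsum(ltDD[1:M])))  # C[k] over k=0..M-1
    for i in range(1, L + 1):
        a = idx[i - 1]
        rm = lrm_full[:, a] if a >= 0 else np.zeros(M)
        ri = lri_full[a] if a >= 0 else 0.0
        prevM, prevI, prevD = vM[i - 1], vI[i - 1], vD[i - 1]
        cand = np.maximum.reduce([
            prevM[:M] + lt[:M, T_MM],
            prevI[:M] + lt[:M, T_IM],
            prevD[:M] + lt[:M, T_DM],
            np.zeros(M),  # fresh local start
        ])
        vM[i, 1:] = rm + cand
        vI[i, :] = ri + np.maximum(prevM + lt[:, T_MI], prevI + lt[:, T_II])
        vI[i, 0] = NEG  # I_0 unreachable in local mode
        seed = vM[i, :M] + lt[:M, T_MD] - C
        vD[i, 1:] = C + np.maximum.accumulate(seed)
    return vM, vI, vD, lt, lrm_full, lri_full


def locate_domain(hmm: ProfileHMM, seq, threshold: float = 180.0):
    """Locate the best-scoring local domain window.

    Runs local-mode Viterbi and returns the maximal-scoring window as a
    :class:`DomainHit` (0-based half-open interval on the query, bits =
    best single-path log2 odds) if its score reaches ``threshold``,
    else ``None``.
    """
    _, idx = _encode(seq)
    vM, vI, vD, lt, lrm, lri = _viterbi_local_matrices(hmm, idx)
    flat = np.argmax(vM)
    i, k = np.unravel_index(flat, vM.shape)
    best = vM[i, k]
    if not (best >= threshold):
        return None
    end = int(i)
    # Traceback to the fresh-start cell, following best predecessors.
    state = "M"
    i, k = int(i), int(k)
    start = None
    for _ in range((vM.shape[0] + vM.shape[1]) * 4):
        if state == "M":
            cands = (
                vM[i - 1, k - 1] + lt[k - 1, T_MM],
                vI[i - 1, k - 1] + lt[k - 1, T_IM],
                vD[i - 1, k - 1] + lt[k - 1, T_DM],
                0.0,
            )
            choice = int(np.argmax(cands))
            if choice == 3:
                start = i - 1
                break
            i, k = i - 1, k - 1
            state = ("M", "I", "D")[choice]
        elif state == "I":
            cands = (vM[i - 1, k] + lt[k, T_MI], vI[i - 1, k] + lt[k, T_II])
            choice = int(np.argmax(cands))
            i = i - 1
            state = ("M", "I")[choice]
        else:  # D
            cands = (vM[i, k - 1] + lt[k - 1, T_MD], vD[i, k - 1] + lt[k - 1, T_DD])
            choice = int(np.argmax(cands))
            k = k - 1
            state = ("M", "D")[choice]
    if start is None:  # pragma: no cover - traceback is bounded by construction
        start = max(0, end - hmm.M)
    return DomainHit(start=start, end=end, bits=float(best))


def sample_sequence(hmm: ProfileHMM, rng, seq_id: str | None = None) -> ProteinSequence:
    """Sample one sequence by stochastic traversal of the model.

    Deterministic given the generator state. Traversals that emit no
    residue (all-delete paths) are redrawn.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    M = hmm.M
    t = hmm.transitions
    letters = np.array(list(AMINO_ACIDS))
    for _attempt in range(1000):
        out = []
        state, node = "M", 0  # begin
        steps = 0
        limit = 10000 + 200 * M
        while steps < limit:
            steps += 1
            if state == "M":
                if node > 0:
                    out.append(letters[rng.choice(N_AA, p=hmm.match_emissions[node - 1])])
                p = t[node, [T_MM, T_MI, T_MD]]
                nxt = rng.choice(3, p=p)
                if nxt == 0:
                    if node == M:
                        break
                    node, state = node + 1, "M"
                elif nxt == 1:
                    state = "I"
                else:
                    if node == M:
                        break
                    node, state = node + 1, "D"
            elif state == "I":
                out.append(letters[rng.choice(N_AA, p=hmm.insert_emissions)])
                p = t[node, [T_IM, T_II]]
                if rng.choice(2, p=p) == 0:
                    if node == M:
                        break
                    node, state = node + 1, "M"
            else:  # D emits nothing
                p = t[node, [T_DM, T_DD]]
                nxt = rng.choice(2, p=p)
                if node == M:
                    break
                node = node + 1
                state = "M" if nxt == 0 else "D"
        if out:
            return ProteinSequence(
                id=seq_id or f"{hmm.name}|sample", residues="".join(out)
            )
    raise ValidationError("model keeps sampling empty sequences")


# ---------------------------------------------------------------------------
# Serialization

def write_profile_json(hmm: ProfileHMM) -> str:
    """Lossless native JSON serialization (schema version 1)."""
    doc = {
        "format": "ksclass-profile",
        "version": _PROFILE_SCHEMA_VERSION,
        "name": hmm.name,
        "M": hmm.M,
        "alphabet": AMINO_ACIDS,
        "match_emissions": hmm.match_emissions.tolist(),
        "insert_emissions": hmm.insert_emissions.tolist(),
        "transitions": hmm.transitions.tolist(),
        "background": hmm.background.tolist(),
    }
    return json.dumps(doc)


def read_profile_json(text: str) -> ProfileHMM:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ProfileParseError(f"invalid JSON: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("format") != "ksclass-profile":
        raise ProfileParseError("not a ksclass profile document")
    if doc.get("version") != _PROFILE_SCHEMA_VERSION:
        raise SchemaVersionError(
            f"unsupported profile schema version {doc.get('version')!r}"
        )
    if doc.get("alphabet") != AMINO_ACIDS:
        raise UnsupportedAlphabetError("profile alphabet is not amino")
    try:
        hmm = ProfileHMM(
            name=doc["name"],
            match_emissions=np.array(doc["match_emissions"], dtype=float),
            insert_emissions=np.array(doc["insert_emissions"], dtype=float),
            transitions=np.array(doc["transitions"], dtype=float),
            background=np.array(doc["background"], dtype=float),
        )
    except KeyError as exc:
        raise ValidationError(f"profile document missing field {exc}") from exc
    if hmm.M != doc.get("M"):
        raise ValidationError("declared M does not match emission rows")
    return hmm


def read_hmmer3_ascii(stream) -> ProfileHMM:
    """Read a HMMER3 ASCII profile (HMMER3/f dialect, amino alphabet).

    Model values are negative natural logs of probabilities; ``*`` encodes
    probability 0 and is floored to 1e-9 before per-group renormalization.
    A COMPO line, when present, supplies the background (else uniform).
    Per-node insert emissions are averaged into the shared insert vector.
    """
    text = stream if isinstance(stream, str) else stream.read()
    lines = text.splitlines()

    def parse_val(tok: str, ln: int) -> float:
        if tok == "*":
            return 0.0
        try:
            return math.exp(-float(tok))
        except ValueError:
            raise ProfileParseError(f"bad model value {tok!r}", line=ln) from None

    name, leng, alph = "hmmer_profile", None, None
    i = 0
    n = len(lines)
    while i < n and not lines[i].startswith("HMM "):
        parts = lines[i].split()
        if parts:
            if parts[0] == "NAME" and len(parts) > 1:
                name = parts[1]
            elif parts[0] == "LENG":
                leng = int(parts[1])
            elif parts[0] == "ALPH":
                alph = parts[1].lower()
        i += 1
    if i >= n:
        raise ProfileParseError("no 'HMM' model section found")
    if alph is not None and alph != "amino":
        raise UnsupportedAlphabetError(f"unsupported alphabet {alph!r}")
    if leng is None:
        raise ProfileParseError("missing LENG header")
    i += 2  # skip the two header lines of the model section

    background = UNIFORM_BACKGROUND.copy()
    if i < n and lines[i].split() and lines[i].split()[0] == "COMPO":
        toks = lines[i].split()[1:]
        if len(toks) < N_AA:
            raise ProfileParseError("short COMPO line", line=i + 1)
        background = np.array([parse_val(tk, i + 1) for tk in toks[:N_AA]])
        background = np.maximum(background, 1e-9)
        background /= background.sum()
        i += 1

    def take_floats(count, ln):
        toks = lines[ln].split()
        if len(toks) < count:
            raise ProfileParseError(
                f"expected {count} values, found {len(toks)}", line=ln + 1
            )
        return [parse_val(tk, ln + 1) for tk in toks[:count]]

    insert_rows = [np.array(take_floats(N_AA, i))]
    trans_rows = [np.array(take_floats(7, i + 1))]
    i += 2
    match_rows = []
    for k in range(1, leng + 1):
        toks = lines[i].split()
        if not toks or toks[0] != str(k):
            raise ProfileParseError(f"expected match line for node {k}", line=i + 1)
        match_rows.append(np.array([parse_val(tk, i + 1) for tk in toks[1 : 1 + N_AA]]))
        insert_rows.append(np.array(take_floats(N_AA, i + 1)))
        trans_rows.append(np.array(take_floats(7, i + 2)))
        i += 3
    if i >= n or lines[i].strip() != "//":
        raise ProfileParseError("missing '//' terminator", line=min(i, n - 1) + 1)

    def floor_norm(a, groups):
        a = np.maximum(np.asarray(a, dtype=float), 1e-9)
        for g in groups:
            a[..., list(g)] = _normalize_rows(a[..., list(g)])
        return a

    match_emissions = floor_norm(np.vstack(match_rows), [tuple(range(N_AA))])
    insert_emissions = floor_norm(
        np.mean(np.vstack(insert_rows), axis=0), [tuple(range(N_AA))]
    )
    transitions = floor_norm(
        np.vstack(trans_rows), [(T_MM, T_MI, T_MD), (T_IM, T_II), (T_DM, T_DD)]
    )
    return ProfileHMM(
        name=name,
        match_emissions=match_emissions,
        insert_emissions=insert_emissions,
        transitions=transitions,
        background=background,
    )


def load_profile(path) -> ProfileHMM:
    """Load a profile from a ``.hmm`` (HMMER3 ASCII) or ``.json`` file."""
    with open(path) as fh:
        text = fh.read()
    if text.lstrip().startswith("HMMER3"):
        return read_hmmer3_ascii(text)
    return read_profile_json(text)
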