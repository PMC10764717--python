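"""Shared test utilities: toy model factories and the path-enumeration
forward oracle (kept independent of the package's DP implementation)."""

from __future__ import annotations

import math

import numpy as np

from ksclass.phmm import (
    AA_INDEX,
    T_DD,
    T_DM,
    T_II,
    T_IM,
    T_MD,
    T_MI,
    T_MM,
    ProfileHMM,
)


def random_model(M: int, seed: int, name: str = "toy") -> ProfileHMM:
    """A random valid profile with Dirichlet emissions/transitions."""
    r = np.random.default_rng(seed)
    me = r.dirichlet(np.ones(20) * 0.5, size=M)
    ie = r.dirichlet(np.ones(20))
    bg = r.dirichlet(np.ones(20) * 5)
    t = np.empty((M + 1, 7))
    t[:, :3] = r.dirichlet([5, 1, 1], size=M + 1)
    t[:, 3:5] = r.dirichlet([3, 2], size=M + 1)
    t[:, 5:7] = r.dirichlet([3, 2], size=M + 1)
    return ProfileHMM(name, me, ie, t, bg)


def single_state_model(p_match: float = 0.95, residue: str = "A") -> ProfileHMM:
    """M=1 model with mass ``p_match`` on one residue, uniform background,
    and a (numerically) forced begin->M1->end path."""
    me = np.full((1, 20), (1.0 - p_match) / 19.0)
    me[0, AA_INDEX[residue]] = p_match
    eps = 1e-12
    node = np.array([1 - 2 * eps, eps, eps, 0.5, 0.5, 0.5, 0.5])
    t = np.tile(node, (2, 1))
    return ProfileHMM("single", me, np.full(20, 0.05), t, np.full(20, 0.05))


def background_equal_model(M: int) -> ProfileHMM:
    """Match emissions equal to (uniform) background; indel-free path of
    length M, so a length-M query is scored by a single forced path."""
    bg = np.full(20, 0.05)
    eps = 1e-12
    node = np.array([1 - 2 * eps, eps, eps, 0.5, 0.5, 0.5, 0.5])
    return ProfileHMM(
        "bg-equal",
        np.tile(bg, (M, 1)),
        bg.copy(),
        np.tile(node, (M + 1, 1)),
        bg.copy(),
    )


def enum_forward_bits(hmm: ProfileHMM, residues: str) -> float:
    """Glocal forward bit score by exhaustive enumeration of every state
    path (depth-first), in emission-odds space. Exponential in size; use
    only for M <= 3 and |seq| <= 5."""
    idx = [AA_INDEX.get(c, -1) for c in residues]
    M, t, bg = hmm.M, hmm.transitions, hmm.background
    L = len(idx)
    total = 0.0

    def em_match(k, a):
        return 1.0 if a < 0 else hmm.match_emissions[k - 1, a] / bg[a]

    def em_ins(a):
        return 1.0 if a < 0 else hmm.insert_emissions[a] / bg[a]

    def rec(state, node, i, weight):
        nonlocal total
        if state == "M":
            outs = (("M", node + 1, t[node, T_MM]), ("I", node, t[node, T_MI]),
                    ("D", node + 1, t[node, T_MD]))
        elif state == "I":
            outs = (("M", node + 1, t[node, T_IM]), ("I", node, t[node, T_II]))
        else:
            outs = (("M", node + 1, t[node, T_DM]), ("D", node + 1, t[node, T_DD]))
        for ns, nn, p in outs:
            w = weight * p
            if nn == M + 1:  # routes to the end state
                if i == L:
                    total += w
                continue
            if ns == "M":
                if i < L:
                    rec("M", nn, i + 1, w * em_match(nn, idx[i]))
            elif ns == "I":
                if i < L:
                    rec("I", nn, i + 1, w * em_ins(idx[i]))
            else:
                rec("D", nn, i, w)

    rec("M", 0, 0, 1.0)
    return math.log2(total)
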