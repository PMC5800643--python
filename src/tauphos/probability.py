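"""Microstate reconstruction from macrostate marginals.

A protein with n phosphorylable sites occupies one of 2^n phosphoform
microstates (a_1…a_n), a_i ∈ {0, 1}.  Tracking them all is combinatorially
hopeless for tau (n ≥ 10); the model therefore integrates only per-site
marginals and reconstructs any microstate on demand under the independence
assumption:

    p(a_1…a_n) = prod_i S(a_i) / S_total

where S(a_i=1) = P_i and S(a_i=0) = S_total − P_i.  For the sequentially
phosphorylated pair (S396 after S404 under GSK3β) independence is violated
by construction — the state (pS396, S404) is unreachable — so a
conditional variant is provided that zeroes that joint cell and assigns
p(a_s=1, a_pre=1) = P_s / S_total, consistent with the gated rate law.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = ["MicrostatePattern", "MacroSummary", "microstate_probability",
           "microstate_concentration", "macro_from_micro",
           "enumerate_patterns", "top_k_microstates"]

#: Guard against accidental enumeration of astronomically many patterns.
MAX_ENUMERATION_SITES = 20


@dataclass(frozen=True)
class MicrostatePattern:
    """Ordered binary site assignment; 1 = phosphorylated."""

    assignment: tuple[int, ...]

    def __post_init__(self):
        if any(a not in (0, 1) for a in self.assignment):
            raise ValueError("assignment entries must be 0 or 1")

    def __len__(self) -> int:
        return len(self.assignment)

    @classmethod
    def from_phosphosites(cls, phosphorylated: Iterable[str],
                          site_order: Sequence[str]) -> "MicrostatePattern":
        """Build a pattern from residue labels, e.g. {"S396", "S404"}."""
        phos = set(phosphorylated)
        unknown = phos - set(site_order)
        if unknown:
            raise KeyError(f"unknown sites: {sorted(unknown)}")
        return cls(tuple(1 if s in phos else 0 for s in site_order))


@dataclass
class MacroSummary:
    """Per-site phosphorylated concentrations P_i and the protein total.

    S(a_i=1) = p[i]; S(a_i=0) = s_total − p[i].
    """

    p: np.ndarray
    s_total: float
    site_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        if self.s_total < 0 or np.any(self.p < -1e-12):
            raise ValueError("concentrations must be nonnegative")
        if np.any(self.p > self.s_total * (1 + 1e-9)):
            raise ValueError("P_i cannot exceed S_total")

    @property
    def n_sites(self) -> int:
        return len(self.p)

    def marginal(self, i: int, value: int) -> float:
        return float(self.p[i] if value == 1 else self.s_total - self.p[i])


def _check(summary: MacroSummary, pattern: MicrostatePattern) -> None:
    if len(pattern) != summary.n_sites:
        raise ValueError("pattern length does not match number of sites")
    if summary.s_total <= 0:
        raise ValueError("S_total must be positive")


def microstate_probability(summary: MacroSummary, pattern: MicrostatePattern,
                           sequential_pairs: Mapping[int, int] | None = None
                           ) -> float:
    """Probability of one phosphoform microstate.

    With ``sequential_pairs`` (map site index → prerequisite index) the
    naive product is replaced, for each pair, by the gated joint law:
    p(1, 0) = 0, p(1, 1) = P_site/S_total, p(0, 1) = (P_pre − P_site)/S_total,
    p(0, 0) = 1 − P_pre/S_total (requires P_site ≤ P_pre, which the gated
    kinetics guarantee).
    """
    _check(summary, pattern)
    sequential_pairs = dict(sequential_pairs or {})
    paired = set(sequential_pairs) | set(sequential_pairs.values())
    st = summary.s_total
    prob = 1.0
    for i, a in enumerate(pattern.assignment):
        if i in paired:
            continue
        prob *= summary.marginal(i, a) / st
    for site, pre in sequential_pairs.items():
        a_s, a_p = pattern.assignment[site], pattern.assignment[pre]
        p_s, p_p = summary.p[site], summary.p[pre]
        if p_s > p_p * (1 + 1e-9) + 1e-12:
            raise ValueError("gated site exceeds its prerequisite level")
        joint = {(1, 0): 0.0, (1, 1): p_s / st, (0, 1): (p_p - p_s) / st,
                 (0, 0): 1.0 - p_p / st}[(a_s, a_p)]
        prob *= max(joint, 0.0)
    return min(max(prob, 0.0), 1.0)


def microstate_concentration(summary: MacroSummary, pattern: MicrostatePattern,
                             sequential_pairs: Mapping[int, int] | None = None
                             ) -> float:
    """Concentration (μM) of one microstate: probability × S_total."""
    return microstate_probability(summary, pattern, sequential_pairs) * summary.s_total


def enumerate_patterns(n_sites: int) -> list[MicrostatePattern]:
    if n_sites > MAX_ENUMERATION_SITES:
        raise ValueError(
            f"refusing to enumerate 2^{n_sites} patterns "
            f"(limit {MAX_ENUMERATION_SITES} sites); query single patterns instead")
    return [MicrostatePattern(bits)
            for bits in itertools.product((0, 1), repeat=n_sites)]


def macro_from_micro(micro: Mapping[tuple[int, ...], float],
                     site_names: Sequence[str] | None = None) -> MacroSummary:
    """Marginalise a microstate concentration table to a MacroSummary."""
    patterns = list(micro)
    if not patterns:
        raise ValueError("empty microstate table")
    n = len(patterns[0])
    p = np.zeros(n)
    s_total = 0.0
    for bits, conc in micro.items():
        if conc < 0:
            raise ValueError("negative microstate concentration")
        if len(bits) != n:
            raise ValueError("inconsistent pattern lengths")
        s_total += conc
        for i, b in enumerate(bits):
            if b == 1:
                p[i] += conc
    return MacroSummary(p=p, s_total=s_total,
                        site_names=list(site_names or []))


def top_k_microstates(summary: MacroSummary, k: int = 10,
                      sequential_pairs: Mapping[int, int] | None = None
                      ) -> list[tuple[MicrostatePattern, float]]:
    """The k most probable microstates, sorted by decreasing probability."""
    pats = enumerate_patterns(summary.n_sites)
    scored = [(pat, microstate_probability(summary, pat, sequential_pairs))
              for pat in pats]
    scored.sort(key=lambda t: (-t[1], t[0].assignment))
    return scored[:k]
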