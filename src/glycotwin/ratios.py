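"""Substrate/product conversion-rate ratios over glycoform space.

Consecutive steps of a glycosylation pathway (e.g. first and second
sialylation of the same backbone) are proxied by the per-individual ratio
of product to substrate relative abundance, computed on untransformed
relative frequencies after outlier removal.  Pairs differing by exactly one
residue of a given type are enumerated exhaustively, linked into multi-step
conversion chains, and adjacent steps are compared with the Wilcoxon test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .glycoforms import GlycoformComposition, parse_glycoform_name
from .multiple_testing import bonferroni_threshold

__all__ = [
    "REACTION_RESIDUE",
    "ReactionStep",
    "ConversionChain",
    "InsufficientPairsError",
    "identify_reaction_pairs",
    "conversion_ratio",
    "build_conversion_chains",
    "compare_consecutive_steps",
    "test_chain_junctions",
]

# reaction type -> residue incremented by one enzymatic step
REACTION_RESIDUE = {
    "sialylation": "S",
    "galactosylation": "H",
    "galnac": "N",           # N-acetylgalactosaminylation
    "fucosylation": "F",
}


class InsufficientPairsError(ValueError):
    pass


@dataclass
class ReactionStep:
    reaction_type: str
    substrate: GlycoformComposition
    product: GlycoformComposition

    def __post_init__(self) -> None:
        res = REACTION_RESIDUE[self.reaction_type]
        if self.substrate.peptide != self.product.peptide:
            raise ValueError("substrate and product must share the peptide")
        for r in "HNFS":
            expect = 1 if r == res else 0
            if getattr(self.product, r) - getattr(self.substrate, r) != expect:
                raise ValueError(
                    f"product must differ from substrate by +1 {res} only")

    def ratios(self, relative: pd.DataFrame) -> np.ndarray:
        return conversion_ratio(relative[str(self.substrate)].to_numpy(float),
                                relative[str(self.product)].to_numpy(float))


@dataclass
class ConversionChain:
    """>= 2 same-type reaction steps where each product feeds the next step."""

    steps: list[ReactionStep]

    def __post_init__(self) -> None:
        if len(self.steps) < 2:
            raise ValueError("a conversion chain needs at least 2 steps")
        types = {s.reaction_type for s in self.steps}
        if len(types) != 1:
            raise ValueError("chain steps must share a reaction type")
        for a, b in zip(self.steps, self.steps[1:]):
            if a.product != b.substrate:
                raise ValueError("chain is not connected")

    @property
    def peptide(self) -> str:
        return self.steps[0].substrate.peptide

    @property
    def reaction_type(self) -> str:
        return self.steps[0].reaction_type

    def __len__(self) -> int:
        return len(self.steps)


def identify_reaction_pairs(
    compositions: list[GlycoformComposition | str],
    reaction_type: str,
) -> list[tuple[GlycoformComposition, GlycoformComposition]]:
    """All same-peptide (substrate, product) pairs differing by +1 residue.

    Deterministic ordering: pairs sorted by substrate composition.
    """
    if reaction_type not in REACTION_RESIDUE:
        raise ValueError(f"unknown reaction type {reaction_type!r}; "
                         f"choose from {sorted(REACTION_RESIDUE)}")
    comps = sorted({c if isinstance(c, GlycoformComposition)
                    else parse_glycoform_name(c) for c in compositions})
    present = set(comps)
    res = REACTION_RESIDUE[reaction_type]
    pairs = []
    for c in comps:
        prod = c.with_added(res)
        if prod in present:
            pairs.append((c, prod))
    return pairs


def conversion_ratio(substrate: np.ndarray, product: np.ndarray) -> np.ndarray:
    """Per-individual product/substrate ratio on relative abundances.

    Individuals with a zero or missing substrate (or missing product) get a
    missing ratio — never infinity.  Raises when every ratio is missing.
    """
    s = np.asarray(substrate, dtype=float)
    p = np.asarray(product, dtype=float)
    if s.shape != p.shape:
        raise ValueError("substrate and product vectors differ in length")
    ok = np.isfinite(s) & np.isfinite(p) & (s > 0)
    out = np.full(s.shape, np.nan)
    out[ok] = p[ok] / s[ok]
    if not ok.any():
        raise ValueError("all conversion ratios are missing")
    return out


def ratio_summary(ratios: np.ndarray) -> dict[str, float]:
    """Median and interquartile range, as displayed on conversion-rate plots."""
    return {
        "n": int(np.isfinite(ratios).sum()),
        "median": float(np.nanmedian(ratios)),
        "q1": float(np.nanpercentile(ratios, 25)),
        "q3": float(np.nanpercentile(ratios, 75)),
    }


def build_conversion_chains(
    pairs: list[tuple[GlycoformComposition, GlycoformComposition]],
    reaction_type: str,
) -> list[ConversionChain]:
    """Maximal paths of length >= 2 in the substrate->product graph.

    For a fixed reaction type each substrate has a unique product, so the
    graph is a union of simple ladders; chains start at substrates that are
    not themselves products.
    """
    succ = {s: p for s, p in pairs}
    products = set(succ.values())
    chains = []
    for start in sorted(s for s in succ if s not in products):
        steps = []
        cur = start
        while cur in succ:
            steps.append(ReactionStep(reaction_type, cur, succ[cur]))
            cur = succ[cur]
        if len(steps) >= 2:
            chains.append(ConversionChain(steps))
    return chains


def compare_consecutive_steps(
    chain: ConversionChain,
    relative: pd.DataFrame,
    paired: bool = True,
    min_pairs: int = 10,
) -> pd.DataFrame:
    """Wilcoxon comparison of ratio distributions at each chain junction.

    Default is the signed-rank test on per-individual paired ratios (the two
    steps are measured in the same individuals); ``paired=False`` uses the
    rank-sum (Mann-Whitney) variant.  Direction compares the later step's
    median against the earlier one's.
    """
    rows = []
    for j, (s1, s2) in enumerate(zip(chain.steps, chain.steps[1:])):
        r1 = s1.ratios(relative)
        r2 = s2.ratios(relative)
        ok = np.isfinite(r1) & np.isfinite(r2)
        if ok.sum() < min_pairs:
            raise InsufficientPairsError(
                f"junction {j}: {int(ok.sum())} paired ratios < {min_pairs}")
        a, b = r1[ok], r2[ok]
        if np.array_equal(a, b):
            p = 1.0
        elif paired:
            p = float(stats.wilcoxon(a, b, zero_method="wilcox").pvalue)
        else:
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        med1, med2 = float(np.median(a)), float(np.median(b))
        direction = ("equal" if med1 == med2
                     else "decrease" if med2 < med1 else "increase")
        rows.append(dict(
            peptide=chain.peptide, reaction_type=chain.reaction_type,
            step_1=f"{s1.substrate}->{s1.product}",
            step_2=f"{s2.substrate}->{s2.product}",
            n=int(ok.sum()), median_1=med1, median_2=med2,
            p=p, direction=direction,
        ))
    return pd.DataFrame(rows)


def test_chain_junctions(
    chains: list[ConversionChain],
    relative: pd.DataFrame,
    alpha: float = 0.05,
    paired: bool = True,
    min_pairs: int = 10,
) -> pd.DataFrame:
    """Junction tests across all chains, Bonferroni-corrected.

    The Bonferroni denominator is the number of junctions actually tested
    in this run (logged in the ``m_tests`` column), never a fixed constant.
    """
    tables = [compare_consecutive_steps(c, relative, paired=paired,
                                        min_pairs=min_pairs) for c in chains]
    if not tables:
        return pd.DataFrame()
    out = pd.concat(tables, ignore_index=True)
    m = len(out)
    thr = bonferroni_threshold(alpha, m)
    out["m_tests"] = m
    out["threshold"] = thr
    out["significant"] = out["p"] < thr
    return out
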