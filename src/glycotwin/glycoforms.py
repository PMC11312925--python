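"""Glycopeptide composition parsing and config-driven derived traits.

Measured glycopeptides are named ``<PEPTIDE>_H<h>N<n>F<f>S<s>`` where the
peptide code is the short amino-acid prefix of the tryptic peptide (e.g. HYT,
LSL, TPL, SES, ENI, LAGC, LAGY) and the four integers count hexoses (H),
N-acetylhexosamines (N), fucoses (F) and sialic acids (S) on the attached
glycan.  Derived traits are weighted sums or ratios of the relative
abundances of structurally related glycoforms on one peptide (e.g. the
fraction of sialylated species, or the mean number of sialic acids per
glycoform).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "GlycoformComposition",
    "DerivedTraitDefinition",
    "parse_glycoform_name",
    "compute_derived_traits",
    "load_trait_definitions",
    "standard_trait_definitions",
]

_NAME_RE = re.compile(r"^(?P<pep>[A-Z]{2,6})_H(?P<H>\d+)N(?P<N>\d+)F(?P<F>\d+)S(?P<S>\d+)$")


@dataclass(frozen=True, order=True)
class GlycoformComposition:
    """Identity of one glycoform: peptide backbone plus monosaccharide counts."""

    peptide: str
    H: int
    N: int
    F: int
    S: int

    def __post_init__(self) -> None:
        if not self.peptide:
            raise ValueError("peptide code must be non-empty")
        for res in "HNFS":
            if getattr(self, res) < 0:
                raise ValueError(f"{res} count must be >= 0")

    def __str__(self) -> str:
        return f"{self.peptide}_H{self.H}N{self.N}F{self.F}S{self.S}"

    def with_added(self, residue: str, delta: int = 1) -> "GlycoformComposition":
        """Return the composition with ``delta`` more of ``residue`` (H/N/F/S)."""
        if residue not in "HNFS":
            raise ValueError(f"unknown residue {residue!r}")
        kwargs = {r: getattr(self, r) for r in "HNFS"}
        kwargs[residue] += delta
        return GlycoformComposition(self.peptide, **kwargs)


def parse_glycoform_name(name: str) -> GlycoformComposition:
    """Parse ``PEP_HhNnFfSs`` into a :class:`GlycoformComposition`.

    Raises ``ValueError`` naming the offending token for malformed input;
    ``str(parse_glycoform_name(x)) == x`` for every valid name.
    """
    m = _NAME_RE.match(name)
    if m is None:
        raise ValueError(f"malformed glycoform name: {name!r} "
                         "(expected <PEPTIDE>_H<int>N<int>F<int>S<int>)")
    return GlycoformComposition(
        m["pep"], H=int(m["H"]), N=int(m["N"]), F=int(m["F"]), S=int(m["S"])
    )


@dataclass
class DerivedTraitDefinition:
    """A named expression over glycoform abundances on a single peptide.

    The trait value is sum(weight * abundance) over the numerator divided by
    the same over the denominator; ``denominator=None`` means a plain
    weighted sum.
    """

    name: str
    peptide: str
    numerator: list[tuple[str, float]]
    denominator: list[tuple[str, float]] | None = None

    def __post_init__(self) -> None:
        for gf, w in self.referenced():
            comp = parse_glycoform_name(gf)
            if comp.peptide != self.peptide:
                raise ValueError(
                    f"trait {self.name!r}: glycoform {gf} is not on peptide {self.peptide}"
                )
            if not np.isfinite(w):
                raise ValueError(f"trait {self.name!r}: non-finite weight for {gf}")

    def referenced(self) -> list[tuple[str, float]]:
        terms = list(self.numerator)
        if self.denominator is not None:
            terms += list(self.denominator)
        return terms


def _weighted_sum(df: pd.DataFrame, terms: list[tuple[str, float]]) -> pd.Series:
    # plain arithmetic (not .sum) so missing values propagate
    out = None
    for gf, w in terms:
        term = df[gf] * w
        out = term if out is None else out + term
    return out


def compute_derived_traits(
    relative: pd.DataFrame,
    definitions: list[DerivedTraitDefinition],
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Evaluate derived-trait definitions on a relative-abundance table.

    Parameters
    ----------
    relative : DataFrame, individuals x glycoforms (stage "relative").
    definitions : trait definitions; every referenced glycoform must be a
        column of ``relative``.

    Returns
    -------
    (traits, zero_denominators) : the individuals x traits table and, per
        ratio trait, the number of individuals whose denominator was zero
        (those entries are set to missing).
    """
    traits = {}
    zero_den: dict[str, int] = {}
    for d in definitions:
        missing_cols = [gf for gf, _ in d.referenced() if gf not in relative.columns]
        if missing_cols:
            raise KeyError(f"trait {d.name!r} references unknown glycoforms: {missing_cols}")
        num = _weighted_sum(relative, d.numerator)
        if d.denominator is None:
            traits[d.name] = num
        else:
            den = _weighted_sum(relative, d.denominator)
            zero = den == 0
            zero_den[d.name] = int(zero.sum())
            traits[d.name] = num / den.where(~zero)
    return pd.DataFrame(traits, index=relative.index), zero_den


def load_trait_definitions(path_or_stream) -> list[DerivedTraitDefinition]:
    """Load trait definitions from a YAML config.

    Schema::

        traits:
          - name: HYT_frac_sialylated
            peptide: HYT
            numerator: {HYT_H3N5F0S1: 1.0, HYT_H3N5F0S2: 1.0}
            denominator: {HYT_H3N5F0S0: 1.0, HYT_H3N5F0S1: 1.0, HYT_H3N5F0S2: 1.0}

    ``denominator`` may be omitted or the literal string ``"1"`` for a
    weighted sum.
    """
    if hasattr(path_or_stream, "read"):
        cfg = yaml.safe_load(path_or_stream)
    else:
        with open(path_or_stream) as fh:
            cfg = yaml.safe_load(fh)
    defs = []
    for entry in cfg["traits"]:
        den = entry.get("denominator")
        if den in (None, "1", 1):
            den_terms = None
        else:
            den_terms = [(gf, float(w)) for gf, w in den.items()]
        defs.append(
            DerivedTraitDefinition(
                name=entry["name"],
                peptide=entry["peptide"],
                numerator=[(gf, float(w)) for gf, w in entry["numerator"].items()],
                denominator=den_terms,
            )
        )
    return defs


def standard_trait_definitions(glycoform_names: list[str]) -> list[DerivedTraitDefinition]:
    """Build an illustrative derived-trait set for a glycoform panel.

    For each peptide present, generates the classic glycosylation-feature
    summaries where the panel supports them: fraction of sialylated /
    fucosylated species, mean sialic acids per glycoform, and mean hexoses
    per glycoform (a galactosylation proxy).  These mirror the feature
    families commonly summarised in Ig glycomics (sialylation,
    fucosylation, galactosylation, bisection); site-specific published
    formula sets can be supplied instead via a YAML config.
    """
    comps = [parse_glycoform_name(n) for n in dict.fromkeys(glycoform_names)]
    by_pep: dict[str, list[GlycoformComposition]] = {}
    for c in comps:
        by_pep.setdefault(c.peptide, []).append(c)
    defs: list[DerivedTraitDefinition] = []
    for pep, forms in sorted(by_pep.items()):
        if len(forms) < 2:
            continue
        allf = [(str(c), 1.0) for c in sorted(forms)]
        if any(c.S >= 1 for c in forms) and any(c.S == 0 for c in forms):
            defs.append(DerivedTraitDefinition(
                name=f"{pep}_frac_sialylated", peptide=pep,
                numerator=[(str(c), 1.0) for c in sorted(forms) if c.S >= 1],
                denominator=allf))
        if len({c.S for c in forms}) > 1:
            defs.append(DerivedTraitDefinition(
                name=f"{pep}_sial_per_glycoform", peptide=pep,
                numerator=[(str(c), float(c.S)) for c in sorted(forms)],
                denominator=allf))
        if any(c.F >= 1 for c in forms) and any(c.F == 0 for c in forms):
            defs.append(DerivedTraitDefinition(
                name=f"{pep}_frac_fucosylated", peptide=pep,
                numerator=[(str(c), 1.0) for c in sorted(forms) if c.F >= 1],
                denominator=allf))
        if len({c.H for c in forms}) > 1:
            defs.append(DerivedTraitDefinition(
                name=f"{pep}_hex_per_glycoform", peptide=pep,
                numerator=[(str(c), float(c.H)) for c in sorted(forms)],
                denominator=allf))
    return defs
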