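"""Analyte registry: chain-length subclasses and internal-standard routing.

Fatty acids are binned by chain length into SCFA (C2–C6), MCFA, LCFA and
VLCFA (≥ C22).  The literature definitions leave gaps (MCFA C8–C14, LCFA
C16–C20), so the default labelling scheme extends each bin to its
neighbour's boundary (MCFA C7–C14, LCFA C15–C21); internal-standard routing
deliberately uses a separate scheme because the quantification recipe routes
C7–C12 acids to the octanoate standard and everything from C13 up to the
palmitate/arachidonate standards by saturation.  Both schemes are plain
dataclasses and can be overridden per run.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, Sequence

from .nomenclature import AcylChain, parse_lipid_name

__all__ = [
    "SCFA", "MCFA", "LCFA", "VLCFA", "POLAR",
    "BoundaryScheme", "LABEL_SCHEME", "IS_SCHEME",
    "AnalyteDef", "InternalStandardDef",
    "classify_fa", "fa_flags", "assign_internal_standard", "panel_census",
    "load_panel", "load_is_map", "fa_molecular_weight",
    "PanelError",
]

SCFA = "SCFA"
MCFA = "MCFA"
LCFA = "LCFA"
VLCFA = "VLCFA"
POLAR = "polar"

OCFA = "OCFA"
PUFA = "PUFA"
DIUNSATURATED = "diunsaturated"
VLC_PUFA = "VLC-PUFA"


class PanelError(ValueError):
    pass


@dataclass(frozen=True)
class BoundaryScheme:
    """Chain-length boundaries (inclusive upper carbon of each bin)."""

    scfa_max: int = 6
    mcfa_max: int = 14
    lcfa_max: int = 21


#: Subclass labelling: SCFA C2-C6, MCFA C7-C14, LCFA C15-C21, VLCFA >= C22.
LABEL_SCHEME = BoundaryScheme()

#: Internal-standard routing: octanoate covers only C7-C12; C13 and longer
#: go to the palmitate (saturated) / arachidonate (unsaturated) standards.
IS_SCHEME = BoundaryScheme(scfa_max=6, mcfa_max=12, lcfa_max=21)


def classify_fa(chain: AcylChain, scheme: BoundaryScheme = LABEL_SCHEME) -> str:
    """Deterministic chain-length subclass of a fatty acid."""
    c = chain.carbons
    if c < 2:
        raise PanelError(f"invalid fatty acid with {c} carbons")
    if c <= scheme.scfa_max:
        return SCFA
    if c <= scheme.mcfa_max:
        return MCFA
    if c <= scheme.lcfa_max:
        return LCFA
    return VLCFA


def fa_flags(chain: AcylChain, scheme: BoundaryScheme = LABEL_SCHEME) -> frozenset:
    """Structural flags: OCFA (odd carbons), PUFA (>=2 C=C), diunsaturated
    (exactly 2), VLC-PUFA (VLCFA and PUFA)."""
    flags = set()
    if chain.carbons % 2 == 1:
        flags.add(OCFA)
    if chain.double_bonds >= 2:
        flags.add(PUFA)
        if chain.double_bonds == 2:
            flags.add(DIUNSATURATED)
        if classify_fa(chain, scheme) == VLCFA:
            flags.add(VLC_PUFA)
    return frozenset(flags)


@dataclass(frozen=True)
class AnalyteDef:
    """One registered organic-acid analyte.

    ``chain`` is set for fatty acids only; polar carboxylic acids carry an
    explicit molecular weight and internal-standard id instead.
    ``mrm_pairs`` holds (Q1, Q3, linear-range tag) tuples; quantification
    picks the pair whose range covers the measured response.
    """

    analyte_id: str
    kind: str  # "fatty acid" | "polar carboxylic acid"
    chain: Optional[AcylChain] = None
    mw: Optional[float] = None
    polar_is_id: Optional[str] = None
    mrm_pairs: tuple = (("Q1", "Q3", "default"),)

    def __post_init__(self):
        if self.kind not in ("fatty acid", "polar carboxylic acid"):
            raise PanelError(f"unknown analyte kind {self.kind!r}")
        if self.kind == "fatty acid" and self.chain is None:
            raise PanelError(f"{self.analyte_id}: fatty acid needs a chain")
        if self.kind == "polar carboxylic acid" and self.mw is None:
            raise PanelError(f"{self.analyte_id}: polar acid needs a molecular weight")
        if not self.mrm_pairs:
            raise PanelError(f"{self.analyte_id}: needs at least one MRM pair")

    @property
    def subclass(self) -> str:
        if self.kind == "polar carboxylic acid":
            return POLAR
        return classify_fa(self.chain)

    @property
    def flags(self) -> frozenset:
        if self.chain is None:
            return frozenset()
        return fa_flags(self.chain)

    @property
    def molecular_weight(self) -> float:
        """g/mol of the underivatized free acid."""
        if self.mw is not None:
            return self.mw
        return fa_molecular_weight(self.chain)


def fa_molecular_weight(chain: AcylChain) -> float:
    """Monoisotopic-agnostic average MW of CnH(2n-2d)O2 in g/mol."""
    n, d = chain.carbons, chain.double_bonds
    return 12.011 * n + 1.008 * (2 * n - 2 * d) + 2 * 15.999


@dataclass(frozen=True)
class InternalStandardDef:
    """A spiked internal standard and the analytes it quantifies.

    ``rule`` is one of scfa / mcfa / saturated_long / unsaturated_long /
    polar; the spiked amount in pmol derives from concentration x volume /
    labelled MW unless overridden.
    """

    is_id: str
    rule: str
    conc_ug_per_ml: float
    spike_volume_ul: float
    mw: float
    spiked_pmol_override: Optional[float] = None

    @property
    def spiked_pmol(self) -> float:
        if self.spiked_pmol_override is not None:
            return self.spiked_pmol_override
        micrograms = self.conc_ug_per_ml * self.spike_volume_ul / 1000.0
        return micrograms / self.mw * 1e6

    def matches(self, analyte: AnalyteDef, scheme: BoundaryScheme = IS_SCHEME) -> bool:
        if self.rule == "polar":
            return (
                analyte.kind == "polar carboxylic acid"
                and analyte.polar_is_id == self.is_id
            )
        if analyte.kind != "fatty acid":
            return False
        sub = classify_fa(analyte.chain, scheme)
        if self.rule == "scfa":
            return sub == SCFA
        if self.rule == "mcfa":
            return sub == MCFA
        long = sub in (LCFA, VLCFA)
        if self.rule == "saturated_long":
            return long and analyte.chain.double_bonds == 0
        if self.rule == "unsaturated_long":
            return long and analyte.chain.double_bonds >= 1
        raise PanelError(f"unknown internal-standard rule {self.rule!r}")


def assign_internal_standard(
    analyte: AnalyteDef,
    is_map: Sequence[InternalStandardDef],
    scheme: BoundaryScheme = IS_SCHEME,
) -> str:
    """Route an analyte to its unique internal standard.

    Raises :class:`PanelError` on an uncovered analyte or an ambiguous map.
    """
    hits = [s.is_id for s in is_map if s.matches(analyte, scheme)]
    if not hits:
        raise PanelError(f"uncovered analyte: {analyte.analyte_id}")
    if len(hits) > 1:
        raise PanelError(
            f"ambiguous map for {analyte.analyte_id}: {', '.join(hits)}"
        )
    return hits[0]


def panel_census(panel: Iterable[AnalyteDef]) -> dict:
    """Distinct-analyte counts per subclass plus their total.

    Omega-isomers (and branched isomers sharing a shorthand) count as
    distinct analytes; duplicate analyte_ids are an error.
    """
    counts = {SCFA: 0, MCFA: 0, LCFA: 0, VLCFA: 0, POLAR: 0}
    seen = set()
    for a in panel:
        if a.analyte_id in seen:
            raise PanelError(f"duplicate analyte_id {a.analyte_id!r}")
        seen.add(a.analyte_id)
        counts[a.subclass] += 1
    counts["total"] = len(seen)
    return counts


# ---------------------------------------------------------------------------
# packaged tables


def _open_data(name: str):
    return resources.files("lipidtiers.data").joinpath(name)


def load_panel(path=None) -> list:
    """Load an analyte panel CSV (default: the packaged branch-C panel,
    a synthetic reconstruction reproducing the reported subclass census)."""
    src = path if path is not None else _open_data("panel_branchC_synthetic.csv")
    out = []
    with open(src, newline="") as fh:
        reader = csv.DictReader(ln for ln in fh if not ln.lstrip().startswith("#"))
        for row in reader:
            kind = row["kind"].strip()
            chain = None
            if kind == "fatty acid":
                sp = parse_lipid_name(row["shorthand"])
                chain = sp.fatty_acyls[0]
            mw = float(row["mw_g_mol"]) if row.get("mw_g_mol") else None
            out.append(
                AnalyteDef(
                    analyte_id=row["analyte_id"].strip(),
                    kind=kind,
                    chain=chain,
                    mw=mw,
                    polar_is_id=(row.get("polar_is_id") or "").strip() or None,
                )
            )
    return out


def load_is_map(path=None) -> list:
    """Load the internal-standard cocktail (default: packaged table)."""
    src = path if path is not None else _open_data("internal_standards.csv")
    out = []
    with open(src, newline="") as fh:
        reader = csv.DictReader(ln for ln in fh if not ln.lstrip().startswith("#"))
        for row in reader:
            out.append(
                InternalStandardDef(
                    is_id=row["is_id"].strip(),
                    rule=row["rule"].strip(),
                    conc_ug_per_ml=float(row["conc_ug_per_ml"]),
                    spike_volume_ul=float(row["spike_volume_ul"]),
                    mw=float(row["mw_g_mol"]),
                )
            )
    return out
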