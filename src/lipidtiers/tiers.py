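"""Three-tier integration: esterified-FA derivation and acyl partitioning.

The workflow quantifies each fatty acid in three complementary ways: its
free pool (tier C, single-injection organic-acid assay), its total pool
after alkaline hydrolysis (tier B), and the esterified acyl composition of
the lipidome (tier A).  The esterified pool is derived by subtraction,

    esterified = total - free,

and each esterified FA is then apportioned among lipid "sinks" (classes,
species, or custom bins such as TG carbon-number bins) by weighting every
resolved species amount with the number of saponifiable acyl slots matching
that FA.  Sphingolipid N-acyls resist alkaline hydrolysis and contribute
zero, so sphingolipid abundance never moves an esterified-FA fraction.

Two denominators are supported: the tier-derived esterified amount (the
workflow's definition; coverage diagnoses how much of it the lipidome
explains) and the lipidome sum itself (fractions then add to one over fully
resolved species).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .nomenclature import (
    AcylChain,
    ClassRegistry,
    LipidSpecies,
    acyl_multiplicity,
    default_registry,
    parse_lipid_name,
)

__all__ = [
    "TiersError",
    "esterified_from_subtraction",
    "partition_fractions",
    "sink_by_class",
    "tg_carbon_bins",
    "partition_flows",
    "TIER_DERIVED",
    "LIPIDOME_SUM",
]

TIER_DERIVED = "tier-derived"
LIPIDOME_SUM = "lipidome-sum"


class TiersError(ValueError):
    pass


def esterified_from_subtraction(
    free: pd.DataFrame,
    total: pd.DataFrame,
    value_col: str = "amount_nmol_per_g",
) -> pd.DataFrame:
    """Build the per-(sample, FA) ledger of free/total/esterified amounts.

    ``free`` (tier C) and ``total`` (tier B) are long tables with columns
    (sample_id, analyte, <value_col>).  Esterified = total - free,
    element-wise; negative differences (possible under measurement noise)
    are clamped to zero and flagged rather than silently absorbed.  FAs
    present in only one tier are returned flagged ``unmatched`` with NaN
    esterified amount and are excluded from partitioning.
    """
    for name, df in (("free", free), ("total", total)):
        for c in ("sample_id", "analyte", value_col):
            if c not in df.columns:
                raise TiersError(f"{name} table lacks column {c!r}")
    f = free.set_index(["sample_id", "analyte"])[value_col]
    t = total.set_index(["sample_id", "analyte"])[value_col]
    if not f.index.is_unique or not t.index.is_unique:
        raise TiersError("duplicate (sample, analyte) rows in tier table")
    idx = f.index.union(t.index)
    fa = f.reindex(idx)
    ta = t.reindex(idx)
    ledger = pd.DataFrame(
        {"free_amount": fa, "total_amount": ta}, index=idx
    ).reset_index()
    unmatched = ledger["free_amount"].isna() | ledger["total_amount"].isna()
    diff = ledger["total_amount"] - ledger["free_amount"]
    clamped = (diff < 0) & ~unmatched
    ledger["esterified_amount"] = diff.clip(lower=0.0)
    ledger.loc[unmatched, "esterified_amount"] = np.nan
    ledger["clamped"] = clamped
    ledger["flag"] = np.where(unmatched, "unmatched", np.where(clamped, "clamped", ""))
    return ledger


def sink_by_class(species: LipidSpecies) -> str:
    """Default sink grouping: the lipid class code."""
    return species.lipid_class.code


def tg_carbon_bins(
    boundary: int = 50,
) -> Callable[[LipidSpecies], str]:
    """Sink grouping splitting TGs by total acyl carbons.

    TGs with total carbons <= ``boundary`` fall in the short-to-medium bin,
    heavier TGs in the long-chain bin (boundary inclusive on the lower bin);
    non-TG species keep their class code as sink.
    """

    def _sink(species: LipidSpecies) -> str:
        if species.lipid_class.code != "TG":
            return species.lipid_class.code
        if species.total_carbons <= boundary:
            return f"TG C<={boundary}"
        return f"TG C>{boundary}"

    return _sink


def partition_fractions(
    lipidome: pd.DataFrame,
    ledger: pd.DataFrame,
    fa: Union[AcylChain, str],
    sinks: Optional[Callable[[LipidSpecies], str]] = None,
    denominator_mode: str = TIER_DERIVED,
    fa_analyte: Optional[str] = None,
    value_col: str = "amount_nmol_per_g",
    registry: Optional[ClassRegistry] = None,
) -> pd.DataFrame:
    """Fractional distribution of one esterified FA among lipid sinks.

    ``lipidome`` is a long tier-A table (sample_id, species, <value_col>).
    Each resolved species contributes amount x saponifiable-acyl
    multiplicity of ``fa`` to its sink; sum-composition species are
    accumulated in ``unresolved_amount`` instead of being attributed.

    Per (sample, sink) the result carries the contribution, the fraction
    under the chosen denominator, plus diagnostics: ``coverage`` =
    lipidome-sum / tier-derived esterified, and the unresolved amount.  A
    non-positive denominator yields NaN fractions flagged
    ``undefined_denominator``.
    """
    if isinstance(fa, str):
        sp = parse_lipid_name(fa, registry)
        chains = sp.fatty_acyls
        if len(chains) != 1:
            raise TiersError(f"query {fa!r} does not name a single fatty acid")
        fa_chain = chains[0]
        fa_analyte = fa_analyte or fa
    else:
        fa_chain = fa
        if fa_analyte is None:
            raise TiersError("fa_analyte required when fa is given as a chain")
    if denominator_mode not in (TIER_DERIVED, LIPIDOME_SUM):
        raise TiersError(f"unknown denominator_mode {denominator_mode!r}")
    sinks = sinks or sink_by_class
    registry = registry or default_registry()
    for c in ("sample_id", "species", value_col):
        if c not in lipidome.columns:
            raise TiersError(f"lipidome table lacks column {c!r}")

    parsed: Dict[str, LipidSpecies] = {}
    for name in lipidome["species"].unique():
        parsed[name] = parse_lipid_name(name, registry)

    records = []
    for sample_id, sub in lipidome.groupby("sample_id", sort=False):
        contrib: Dict[str, float] = {}
        unresolved = 0.0
        lipidome_sum = 0.0
        for row in sub.itertuples(index=False):
            species = parsed[row.species]
            amount = getattr(row, value_col)
            if not species.resolved:
                # only classes whose slots hydrolyse could hide this FA
                if species.lipid_class.saponifiable_slots > 0:
                    unresolved += amount
                continue
            mult = acyl_multiplicity(species, fa_chain, saponifiable_only=True)
            if mult == 0:
                continue
            c = amount * mult
            contrib[sinks(species)] = contrib.get(sinks(species), 0.0) + c
            lipidome_sum += c

        est = np.nan
        led = ledger[
            (ledger["sample_id"] == sample_id)
            & (ledger["analyte"] == fa_analyte)
        ]
        if len(led) == 1:
            est = float(led["esterified_amount"].iloc[0])

        denom = est if denominator_mode == TIER_DERIVED else lipidome_sum
        ok = np.isfinite(denom) and denom > 0
        coverage = lipidome_sum / est if np.isfinite(est) and est > 0 else np.nan
        for sink, c in sorted(contrib.items()):
            records.append(
                {
                    "sample_id": sample_id,
                    "fa": fa_analyte,
                    "sink": sink,
                    "contribution": c,
                    "fraction": c / denom if ok else np.nan,
                    "denominator_mode": denominator_mode,
                    "denominator": denom if np.isfinite(denom) else np.nan,
                    "coverage": coverage,
                    "unresolved_amount": unresolved,
                    "flag": "" if ok else "undefined_denominator",
                }
            )
        if not contrib:
            records.append(
                {
                    "sample_id": sample_id,
                    "fa": fa_analyte,
                    "sink": None,
                    "contribution": 0.0,
                    "fraction": np.nan,
                    "denominator_mode": denominator_mode,
                    "denominator": denom if np.isfinite(denom) else np.nan,
                    "coverage": coverage,
                    "unresolved_amount": unresolved,
                    "flag": "no_contributing_species",
                }
            )
    return pd.DataFrame.from_records(records)


def partition_flows(
    partitions: Mapping[str, pd.DataFrame],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Combine per-condition partition tables into a long flow table.

    ``partitions`` maps condition label -> the per-sample output of
    :func:`partition_fractions` (same FA and sink grouping everywhere).
    Rows are (condition, fa, sink) with the mean fraction, its SEM and n;
    when exactly two conditions are given, per-sink deltas (second minus
    first) and two-sided Student t-test p-values are appended.  Suitable for
    Sankey or bar rendering.
    """
    from .stats import students_t

    if not partitions:
        raise TiersError("no partition tables given")
    sink_sets = {
        cond: frozenset(df.loc[df["sink"].notna(), "sink"])
        for cond, df in partitions.items()
    }
    ref = None
    for cond, s in sink_sets.items():
        if ref is None:
            ref = s
        elif s != ref:
            raise TiersError(
                f"mismatched sink sets across conditions: {cond} has {sorted(s)}"
            )

    rows = []
    for cond, df in partitions.items():
        for (fa_id, sink), sub in df[df["sink"].notna()].groupby(["fa", "sink"]):
            vals = sub["fraction"].dropna().to_numpy()
            rows.append(
                {
                    "condition": cond,
                    "fa": fa_id,
                    "sink": sink,
                    "mean_fraction": vals.mean() if vals.size else np.nan,
                    "sem_fraction": (
                        vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else np.nan
                    ),
                    "n": int(vals.size),
                }
            )
    flow = pd.DataFrame.from_records(rows)

    conds = list(partitions)
    if len(conds) == 2:
        a, b = conds
        deltas = []
        for (fa_id, sink), _ in flow.groupby(["fa", "sink"]):
            va = partitions[a]
            va = va[(va["fa"] == fa_id) & (va["sink"] == sink)]["fraction"].dropna()
            vb = partitions[b]
            vb = vb[(vb["fa"] == fa_id) & (vb["sink"] == sink)]["fraction"].dropna()
            delta = vb.mean() - va.mean()
            if len(va) >= 2 and len(vb) >= 2:
                _, p = students_t(va.to_numpy(), vb.to_numpy())
            else:
                p = np.nan
            deltas.append(
                {
                    "fa": fa_id,
                    "sink": sink,
                    "delta": delta,
                    "p_value": p,
                    "significant": bool(p < alpha) if np.isfinite(p) else False,
                }
            )
        flow = flow.merge(pd.DataFrame.from_records(deltas), on=["fa", "sink"], how="left")
    return flow
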