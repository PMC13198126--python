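"""Ground-truthed synthetic three-tier data for end-to-end testing.

The generator emulates the statistical structure the workflow assumes, not
chromatography: per sample it draws a tissue with known free FA amounts and
a known lipidome (resolved acyl compositions), derives the esterified and
total FA pools by construction,

    total = free + sum over species of amount x saponifiable multiplicity,

and renders MRM peak areas for the three tiers through a proportional
response model (area = response factor x amount, shared across tiers by
default) with multiplicative log-normal noise — the standard error model
for MS peak areas.  Internal-standard areas are rendered through the same
model from the spiked amounts, so quantification inverts the forward model
exactly in the noiseless limit and the IS ratio cancels any rescaling of
response factors.

Group effects are multiplicative on the true amounts (e.g. an aged-group
TG enrichment), which makes injected fold changes recoverable as fold
changes of group means.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .nomenclature import AcylChain, acyl_multiplicity, parse_lipid_name
from .panel import load_is_map, load_panel

__all__ = [
    "SimulationSpec",
    "GroundTruth",
    "default_spec",
    "simulate_tissue",
    "render_peak_areas",
    "simulate_calibration",
    "CALIBRATION_LEVELS_MG_L",
]

#: Default calibration grid: serial dilution from 0.0005 to 0.25 mg/L.
CALIBRATION_LEVELS_MG_L = (0.0005, 0.001, 0.0025, 0.005, 0.01, 0.025, 0.05, 0.1, 0.25)

LIPIDOME_IS = "IS_lipidome"


@dataclass(frozen=True)
class SimulationSpec:
    """Everything that determines one synthetic study (seed included).

    Amounts are nmol/g tissue; group effects are multipliers applied to the
    named analyte (free FA) or species amount in that group; response
    factors are area units per pmol.  ``noise_sd`` is the standard
    deviation of the underlying normal of the multiplicative log-normal
    noise (0 = noiseless); ``baseline`` an optional additive area offset.
    ``tier_response_scale`` stress-tests denominator modes by scaling the
    shared response factor per tier.
    """

    seed: int = 0
    groups: Tuple[Tuple[str, int], ...] = (("young", 4), ("old", 4))
    free_amounts: Tuple[Tuple[str, float], ...] = ()
    lipidome: Tuple[Tuple[str, float], ...] = ()
    group_effects: Tuple[Tuple[str, str, float], ...] = ()  # (group, name, multiplier)
    response_factors: Tuple[Tuple[str, float], ...] = ()
    default_response_factor: float = 2000.0
    tier_response_scale: Tuple[Tuple[str, float], ...] = ()
    noise_sd: float = 0.05
    baseline: float = 0.0
    tissue_mass_mg: float = 30.0
    lipidome_is_pmol: float = 1000.0

    def rf(self, name: str) -> float:
        return dict(self.response_factors).get(name, self.default_response_factor)

    def tier_scale(self, tier: str) -> float:
        return dict(self.tier_response_scale).get(tier, 1.0)

    def effect(self, group: str, name: str) -> float:
        return dict(
            ((g, n), m) for g, n, m in self.group_effects
        ).get((group, name), 1.0)


def default_spec(seed: int = 0, noise_sd: float = 0.05) -> SimulationSpec:
    """The packaged study conditions: 4 young vs 4 old samples, ~30 mg
    tissue, an 8-FA panel subset with a resolved glycerolipid lipidome plus
    sphingolipids, and aging effects enriching TGs (strongest for the
    odd-chain 17:1-containing TG) and free 18:1."""
    free = (
        ("FA 16:0", 50.0),
        ("FA 16:1 n-9", 10.0),
        ("FA 17:1", 4.0),
        ("FA 18:0", 30.0),
        ("FA 18:1 n-9", 60.0),
        ("FA 18:2", 25.0),
        ("FA 20:4 n-6", 12.0),
        ("FA 22:6", 8.0),
    )
    lipidome = (
        ("TG 52:2(16:0_18:1_18:1)", 30.0),
        ("TG 50:1(16:0_16:0_18:1)", 20.0),
        ("TG 52:3(16:0_18:1_18:2)", 15.0),
        ("TG 49:1(16:0_16:0_17:1)", 5.0),
        ("DG 36:3(18:2_18:1)", 5.0),
        ("DG 34:1(16:0_18:1)", 6.0),
        ("PC 34:1(16:0_18:1)", 40.0),
        ("PC 36:4(16:0_20:4)", 25.0),
        ("PC 32:0(16:0_16:0)", 18.0),
        ("PE 38:4(18:0_20:4)", 20.0),
        ("PE 38:6(16:0_22:6)", 12.0),
        ("PE 40:6(18:0_22:6)", 10.0),
        ("PI 38:4(18:0_20:4)", 8.0),
        ("PI 36:3(18:2_18:1)", 5.0),
        ("PS 36:1(18:0_18:1)", 7.0),
        ("SM 33:1;O2", 6.0),
        ("Cer d18:1/17:0", 3.0),
    )
    effects = (
        ("old", "TG 49:1(16:0_16:0_17:1)", 2.5),
        ("old", "TG 52:2(16:0_18:1_18:1)", 2.0),
        ("old", "TG 50:1(16:0_16:0_18:1)", 2.0),
        ("old", "DG 36:3(18:2_18:1)", 1.5),
        ("old", "FA 18:1 n-9", 1.3),
        ("old", "SM 33:1;O2", 1.5),
    )
    return SimulationSpec(
        seed=seed,
        free_amounts=free,
        lipidome=lipidome,
        group_effects=effects,
        noise_sd=noise_sd,
    )


@dataclass(frozen=True)
class GroundTruth:
    """True per-sample amounts (nmol/g), conserved by construction."""

    samples: pd.DataFrame  # sample_id, group
    free: pd.DataFrame  # sample_id, analyte, amount
    species: pd.DataFrame  # sample_id, species, amount
    esterified: pd.DataFrame  # sample_id, analyte, amount
    total: pd.DataFrame  # sample_id, analyte, amount


def simulate_tissue(spec: SimulationSpec) -> GroundTruth:
    """Generate the true free / species / esterified / total amounts.

    The esterified pool of each FA is the multiplicity-weighted sum of the
    saponifiable lipidome; totals are free + esterified.  Fully
    deterministic given the spec (group effects only; measurement noise
    enters at rendering).
    """
    chains: Dict[str, AcylChain] = {}
    for fa_name, _ in spec.free_amounts:
        sp = parse_lipid_name(fa_name)
        chains[fa_name] = sp.fatty_acyls[0]
    parsed = {name: parse_lipid_name(name) for name, _ in spec.lipidome}

    samples, free_rows, sp_rows, est_rows, tot_rows = [], [], [], [], []
    for group, n in spec.groups:
        for i in range(1, n + 1):
            sid = f"{group}_{i}"
            samples.append({"sample_id": sid, "group": group})
            sp_amounts = {
                name: amt * spec.effect(group, name) for name, amt in spec.lipidome
            }
            for name, amt in sp_amounts.items():
                sp_rows.append(
                    {"sample_id": sid, "species": name, "amount": amt}
                )
            for fa_name, famt in spec.free_amounts:
                free_amt = famt * spec.effect(group, fa_name)
                est = sum(
                    amt * acyl_multiplicity(parsed[name], chains[fa_name])
                    for name, amt in sp_amounts.items()
                )
                free_rows.append(
                    {"sample_id": sid, "analyte": fa_name, "amount": free_amt}
                )
                est_rows.append({"sample_id": sid, "analyte": fa_name, "amount": est})
                tot_rows.append(
                    {"sample_id": sid, "analyte": fa_name, "amount": free_amt + est}
                )
    return GroundTruth(
        samples=pd.DataFrame(samples),
        free=pd.DataFrame(free_rows),
        species=pd.DataFrame(sp_rows),
        esterified=pd.DataFrame(est_rows),
        total=pd.DataFrame(tot_rows),
    )


def _noise(rng: np.random.Generator, sd: float, size=None):
    if sd == 0:
        return 1.0 if size is None else np.ones(size)
    return np.exp(rng.normal(0.0, sd, size=size))


def render_peak_areas(
    truth: GroundTruth,
    spec: SimulationSpec,
    is_map=None,
    rng: Optional[np.random.Generator] = None,
) -> Dict[str, pd.DataFrame]:
    """Render the three tier peak-area tables (plus IS rows) from truth.

    Tier C areas come from the free pool, tier B from the total pool, tier
    A from species amounts with a single spiked lipidome standard.  Every
    area is response factor x amount_pmol x log-normal noise + baseline;
    amounts convert to pmol via the tissue mass (nmol/g x mg = pmol).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    is_map = is_map if is_map is not None else load_is_map()
    group_of = dict(zip(truth.samples["sample_id"], truth.samples["group"]))
    mass = spec.tissue_mass_mg

    def rows_for(tier: str, table: pd.DataFrame, name_col: str):
        scale = spec.tier_scale(tier)
        out = []
        for r in table.itertuples(index=False):
            name = getattr(r, name_col)
            pmol = r.amount * mass
            area = spec.rf(name) * scale * pmol * float(_noise(rng, spec.noise_sd))
            out.append(
                {
                    "sample_id": r.sample_id,
                    "tier": tier,
                    "analyte": name,
                    "transition": "T1",
                    "area": area + spec.baseline,
                    "tissue_mass_mg": mass,
                    "group": group_of[r.sample_id],
                }
            )
        # internal standards, same response model
        for sid in truth.samples["sample_id"]:
            if tier in ("B", "C"):
                for s in is_map:
                    area = (
                        spec.rf(s.is_id)
                        * scale
                        * s.spiked_pmol
                        * float(_noise(rng, spec.noise_sd))
                    )
                    out.append(
                        {
                            "sample_id": sid,
                            "tier": tier,
                            "analyte": s.is_id,
                            "transition": "T1",
                            "area": area + spec.baseline,
                            "tissue_mass_mg": mass,
                            "group": group_of[sid],
                        }
                    )
            else:
                area = (
                    spec.rf(LIPIDOME_IS)
                    * scale
                    * spec.lipidome_is_pmol
                    * float(_noise(rng, spec.noise_sd))
                )
                out.append(
                    {
                        "sample_id": sid,
                        "tier": tier,
                        "analyte": LIPIDOME_IS,
                        "transition": "T1",
                        "area": area + spec.baseline,
                        "tissue_mass_mg": mass,
                        "group": group_of[sid],
                    }
                )
        return pd.DataFrame(out)

    return {
        "A": rows_for("A", truth.species, "species"),
        "B": rows_for("B", truth.total, "analyte"),
        "C": rows_for("C", truth.free, "analyte"),
    }


def quantify_lipidome_table(
    tier_a: pd.DataFrame,
    spec_is_pmol: float,
    is_id: str = LIPIDOME_IS,
) -> pd.DataFrame:
    """Invert the tier-A rendering: species amounts by IS ratio.

    Returns (sample_id, species, amount_nmol_per_g, plus metadata).
    """
    is_rows = tier_a[tier_a["analyte"] == is_id].set_index("sample_id")["area"]
    out = []
    for r in tier_a[tier_a["analyte"] != is_id].itertuples(index=False):
        a_is = is_rows.get(r.sample_id, np.nan)
        pmol = r.area / a_is * spec_is_pmol if a_is and np.isfinite(a_is) else np.nan
        rec = {
            "sample_id": r.sample_id,
            "species": r.analyte,
            "amount_nmol_per_g": pmol / r.tissue_mass_mg,
        }
        if hasattr(r, "group"):
            rec["group"] = r.group
        out.append(rec)
    return pd.DataFrame(out)


def simulate_calibration(
    slope: float,
    sigma: float,
    intercept: float = 0.0,
    levels_mg_l: Sequence[float] = CALIBRATION_LEVELS_MG_L,
    mw: float = 256.43,
    replicates: int = 1,
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Render a calibration series with known slope and residual scale.

    ``slope`` is the response per mmol/L, ``sigma`` the Gaussian residual
    standard deviation of the areas, so the analytic detection limit of the
    generating process is 3.3 sigma / slope.  Returns (levels_mg_l, areas).
    """
    if len(levels_mg_l) < 3:
        raise ValueError("calibration needs >= 3 levels")
    if rng is None:
        rng = np.random.default_rng(seed)
    x_mg = np.repeat(np.asarray(levels_mg_l, dtype=float), replicates)
    x = x_mg / mw
    areas = intercept + slope * x + rng.normal(0.0, sigma, size=x.size)
    return x_mg, areas
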