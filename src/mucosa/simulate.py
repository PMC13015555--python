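"""Seeded generators emulating every pipeline input, with ground truth.

The study data these generators stand in for are not publicly released,
so each generator is a declared synthetic emulation of one input kind:
serology OD tables, adhesion/reporter plates, monoclonal standard curves,
treatment-structured expression matrices, and two-genotype swiss-roll
spatial cell tables.  Every generator is a pure function of its spec
(including the seed): the same spec yields a bit-identical table.  Truth
objects are returned separately and are consumed only by tests and
acceptance checks, never by the analysis operations.

Default parameters are fixed study conditions, not tuning dials: the
serology cohort mirrors the analysed cohort structure (338 healthy
subjects, 194 UC, IgG positive fractions 89.2% / 11.5%); the adhesion
assay uses 3 replicate wells per arm with 10% replicate CV; the
swiss-roll geometry is an Archimedean spiral of pitch 2*pi*110 um with a
250 um tissue half-thickness and 20 um radial placement jitter, carrying
a rare mid-colon canonical goblet cluster that doubles in density in the
knockout genotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .serology import _fourpl
from .unroll import TWO_PI, archimedean_arc_length, assign_regions

__all__ = [
    "CohortSpec",
    "AssaySpec",
    "ExpressionSimSpec",
    "SpatialSimSpec",
    "simulate_serology",
    "simulate_adhesion",
    "simulate_reporter",
    "simulate_expression",
    "simulate_swiss_roll",
    "simulate_standard_curve",
]


# ---------------------------------------------------------------------------
# serology
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSpec:
    """Serology cohort: log-normal OD mixtures per group.

    ``od_null`` / ``od_pos`` are (log-median, log-SD) of the seronegative
    and seropositive OD distributions (ODs are positive and right-skewed,
    hence log-normal).
    """

    n_hs: int = 338
    n_uc: int = 194
    od_null: tuple[float, float] = (float(np.log(0.08)), 0.45)
    od_pos: tuple[float, float] = (float(np.log(0.9)), 0.5)
    positive_fraction_uc: float = 0.892
    positive_fraction_hs: float = 0.115
    isotype: str = "IgG"
    antigen: str = "avb6_human"
    dilution: float = 100.0
    seed: int = 0


def simulate_serology(spec: CohortSpec):
    """Serum measurement table plus per-subject truth labels."""
    for f in (spec.positive_fraction_uc, spec.positive_fraction_hs):
        if not 0.0 <= f <= 1.0:
            raise ValueError("positive fractions must lie in [0, 1]")
    if spec.od_null[1] <= 0 or spec.od_pos[1] <= 0:
        raise ValueError("log-SD scales must be > 0")
    rng = np.random.default_rng(spec.seed)
    rows, truth = [], []
    for group, n, frac in (
        ("HS", spec.n_hs, spec.positive_fraction_hs),
        ("UC", spec.n_uc, spec.positive_fraction_uc),
    ):
        is_pos = rng.random(n) < frac
        mu = np.where(is_pos, spec.od_pos[0], spec.od_null[0])
        sd = np.where(is_pos, spec.od_pos[1], spec.od_null[1])
        od = np.exp(rng.normal(mu, sd))
        for i in range(n):
            sid = f"{group}{i:04d}"
            rows.append(
                {
                    "subject_id": sid,
                    "group": group,
                    "isotype": spec.isotype,
                    "antigen": spec.antigen,
                    "od": od[i],
                    "dilution": spec.dilution,
                }
            )
            truth.append({"subject_id": sid, "true_positive": bool(is_pos[i])})
    return pd.DataFrame(rows), pd.DataFrame(truth).set_index("subject_id")


# ---------------------------------------------------------------------------
# adhesion / reporter plates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AssaySpec:
    """Adhesion assay cohort with planted inhibitory sera.

    Each test serum gets its own plate holding untreated wells, HS serum
    wells at adherence 1 +/- CV, and the test serum's wells at
    ``adherence_ratio`` +/- CV (inhibitors) or 1 +/- CV (nulls).
    """

    n_samples: int = 29
    n_true_inhibitors: int = 10
    adherence_ratio: float = 0.5
    replicate_cv: float = 0.1
    replicates_per_arm: int = 3
    n_untreated: int = 3
    scale: float = 1000.0
    seed: int = 0


def simulate_adhesion(spec: AssaySpec):
    """Per-well adhesion table, HS sample ids, and the true inhibitor set."""
    if spec.n_true_inhibitors > spec.n_samples:
        raise ValueError("n_true_inhibitors cannot exceed n_samples")
    if spec.replicate_cv < 0 or not 0 < spec.adherence_ratio <= 1:
        raise ValueError("invalid assay spec")
    rng = np.random.default_rng(spec.seed)
    inhibitors = {f"UC{i:04d}" for i in range(spec.n_true_inhibitors)}
    hs_ids = [f"HS{j}" for j in range(spec.replicates_per_arm)]
    rows = []

    def wells(plate, condition, sample, mean, n):
        noise = mean * spec.replicate_cv
        vals = np.maximum(rng.normal(mean, noise, size=n), 0.0)
        for w, v in enumerate(vals):
            rows.append(
                {
                    "plate_id": plate,
                    "well_id": f"{condition[:2].upper()}{w}",
                    "condition": condition,
                    "sample_id": sample,
                    "dilution": 100.0,
                    "adherent": v,
                }
            )

    for i in range(spec.n_samples):
        sid = f"UC{i:04d}"
        plate = f"P{i:03d}"
        wells(plate, "untreated", None, spec.scale, spec.n_untreated)
        for j, hs in enumerate(hs_ids):
            noise = spec.scale * spec.replicate_cv
            v = max(rng.normal(spec.scale, noise), 0.0)
            rows.append(
                {
                    "plate_id": plate,
                    "well_id": f"HS{j}",
                    "condition": "serum",
                    "sample_id": hs,
                    "dilution": 100.0,
                    "adherent": v,
                }
            )
        mean = spec.scale * (spec.adherence_ratio if sid in inhibitors else 1.0)
        wells(plate, "serum", sid, mean, spec.replicates_per_arm)
    return pd.DataFrame(rows), hs_ids, inhibitors


def simulate_reporter(
    n_hs: int = 6,
    n_uc: int = 6,
    reduction: float = 0.4,
    cv: float = 0.05,
    replicates: int = 3,
    scale: float = 1.0,
    seed: int = 0,
):
    """Reporter plate (OD620) with a planted fractional reduction in UC."""
    rng = np.random.default_rng(seed)
    rows = []
    for group, n, mean in (("HS", n_hs, scale), ("UC", n_uc, scale * (1 - reduction))):
        for i in range(n):
            vals = rng.normal(mean, mean * cv, size=replicates)
            for w, v in enumerate(vals):
                rows.append(
                    {
                        "plate_id": "R0",
                        "well_id": f"{group}{i}_{w}",
                        "condition": "igg",
                        "sample_id": f"{group}{i:03d}",
                        "od620": v,
                    }
                )
    hs_ids = [f"HS{i:03d}" for i in range(n_hs)]
    return pd.DataFrame(rows), hs_ids


# ---------------------------------------------------------------------------
# expression matrices with planted lineage effects
# ---------------------------------------------------------------------------


def _default_effects():
    return {
        "tgfb": {"goblet": -1.0, "absorptive": -1.0, "stem": 0.5},
        "anti_avb6": {"goblet": 1.0, "absorptive": 1.0, "stem": -0.5},
    }


@dataclass(frozen=True)
class ExpressionSimSpec:
    """Treatment-structured expression matrix with planted set shifts.

    ``effects`` maps treatment -> {subset -> effect in SD units}; an
    'untreated' arm is always generated.  Signs default to TGF-beta
    suppressing goblet/absorptive programs and alpha-v-beta-6 blockade
    inducing them, with stem signatures moving oppositely.
    """

    n_genes: int = 200
    markers_per_set: int = 15
    samples_per_arm: int = 3
    noise_sd: float = 1.0
    effects: dict = field(default_factory=_default_effects)
    seed: int = 0


def simulate_expression(spec: ExpressionSimSpec):
    """Returns (matrix, gene_sets, sample_sheet, truth effects).

    Baseline values are standard normal on the log2 scale; marker genes of
    each subset are shifted by ``effect * noise_sd`` in the corresponding
    treatment arm.  ``gene_sets`` is a GMT-compatible {name: [genes]}.
    """
    if spec.samples_per_arm < 2:
        raise ValueError("need >= 2 samples per arm")
    subsets = sorted({s for eff in spec.effects.values() for s in eff})
    if spec.n_genes < spec.markers_per_set * len(subsets):
        raise ValueError("n_genes too small for the requested marker sets")
    rng = np.random.default_rng(spec.seed)
    genes = [f"G{i:05d}" for i in range(spec.n_genes)]
    gene_sets = {
        subset: genes[i * spec.markers_per_set:(i + 1) * spec.markers_per_set]
        for i, subset in enumerate(subsets)
    }
    treatments = ["untreated", *sorted(spec.effects)]
    columns, labels = [], {}
    data = []
    for t in treatments:
        for k in range(spec.samples_per_arm):
            name = f"{t}_{k}"
            columns.append(name)
            labels[name] = t
            col = rng.normal(0.0, spec.noise_sd, size=spec.n_genes)
            for subset, eff in spec.effects.get(t, {}).items():
                idx = [genes.index(g) for g in gene_sets[subset]]
                col[idx] += eff * spec.noise_sd
            data.append(col)
    matrix = pd.DataFrame(np.column_stack(data), index=genes, columns=columns)
    sheet = pd.Series(labels, name="treatment")
    return matrix, gene_sets, sheet, dict(spec.effects)


# ---------------------------------------------------------------------------
# swiss-roll spatial data
# ---------------------------------------------------------------------------


def _default_layout():
    # name -> (s_lo, s_hi, d_lo, d_hi, weight); weights renormalised
    return {
        "smooth_muscle": (0.0, 1.0, 0.0, 0.06, 0.08),
        "proliferating_gc": (0.0, 1.0, 0.05, 0.35, 0.10),
        "enterocyte": (0.0, 1.0, 0.20, 1.0, 0.42),
        "canonical_gc_mid": (1.0 / 3.0, 2.0 / 3.0, 0.20, 0.60, 0.01),
        "noncanonical_gc": (0.30, 1.0, 0.30, 0.80, 0.16),
        "intercrypt_gc": (2.0 / 3.0, 1.0, 0.88, 1.0, 0.11),
        "plasma_b": (0.0, 1.0, 0.05, 0.50, 0.12),
    }


@dataclass(frozen=True)
class SpatialSimSpec:
    """Two-genotype swiss-roll sections with known (s, d) ground truth.

    The colon of ``colon_length`` um is wound onto the Archimedean spiral
    r = a + b*theta starting at ``theta0`` (inner terminus = distal end).
    Cells are drawn per cluster from the (s, d) layout, mapped onto the
    spiral at radius r(theta) + (d - 0.5) * 2 * half_thickness, and
    jittered radially (Gaussian) and tangentially (small uniform angle).
    ``knockout_expansion`` multiplies the density of ``expanded_clusters``
    in the knockout genotype; the default expanded cluster is confined to
    the mid third of the colon.
    """

    colon_length: float = 60000.0
    a: float = 400.0
    b: float = 110.0
    theta0: float = TWO_PI
    half_thickness: float = 250.0
    cells_per_mm: float = 400.0
    layout: dict = field(default_factory=_default_layout)
    knockout_expansion: float = 2.0
    expanded_clusters: tuple[str, ...] = ("canonical_gc_mid",)
    jitter_r: float = 20.0
    jitter_theta: float = 0.002
    n_samples_per_genotype: int = 2
    luminal_sign: int = 1
    with_counts: bool = False
    seed: int = 0


_COUNT_RATES = {
    # gene -> {cluster: Poisson rate}; sparse everywhere else
    "Retnlb": {"canonical_gc_mid": 4.0},
    "Ang4": {"canonical_gc_mid": 3.0, "noncanonical_gc": 0.3},
    "Aqp8": {"intercrypt_gc": 4.0, "enterocyte": 0.5},
    "Muc2": {
        "canonical_gc_mid": 5.0,
        "noncanonical_gc": 5.0,
        "intercrypt_gc": 5.0,
        "proliferating_gc": 2.0,
    },
}


def _theta_end(spec: SpatialSimSpec) -> float:
    target = archimedean_arc_length(spec.a, spec.b, spec.theta0) + spec.colon_length
    sol = optimize.brentq(
        lambda t: archimedean_arc_length(spec.a, spec.b, t) - target,
        spec.theta0,
        spec.theta0 + 400.0,
    )
    return float(sol)


def simulate_swiss_roll(spec: SpatialSimSpec):
    """Returns (cells, truth[, counts]) for a two-genotype experiment.

    ``cells`` has cell_id, sample_id, genotype, x, y (um) and cluster;
    ``truth`` carries the generating (s, d, region, cluster) per cell.
    ``counts`` (cells x genes) is included when ``spec.with_counts``.
    """
    if spec.half_thickness * 2.0 >= TWO_PI * spec.b:
        raise ValueError("tissue band thicker than the spiral pitch")
    for name, (s0, s1, d0, d1, w) in spec.layout.items():
        if not (0 <= s0 < s1 <= 1 and 0 <= d0 < d1 <= 1 and w >= 0):
            raise ValueError(f"invalid layout for cluster {name!r}")
    theta1 = _theta_end(spec)
    rng = np.random.default_rng(spec.seed)
    n_cells = int(round(spec.cells_per_mm * spec.colon_length / 1000.0))

    # dense inverse arc-length table
    grid_t = np.linspace(spec.theta0, theta1, 8192)
    grid_l = archimedean_arc_length(spec.a, spec.b, grid_t)
    grid_l = grid_l - grid_l[0]
    total = grid_l[-1]

    names = sorted(spec.layout)
    cell_rows, truth_rows, count_rows = [], [], []
    for genotype in ("control", "knockout"):
        weights = np.array([spec.layout[n][4] for n in names], dtype=float)
        if genotype == "knockout":
            for j, n in enumerate(names):
                if n in spec.expanded_clusters:
                    weights[j] *= spec.knockout_expansion
        weights = weights / weights.sum()
        for rep in range(spec.n_samples_per_genotype):
            sample_id = f"{genotype}_{rep}"
            which = rng.choice(len(names), size=n_cells, p=weights)
            s0 = np.array([spec.layout[names[j]][0] for j in which])
            s1 = np.array([spec.layout[names[j]][1] for j in which])
            d0 = np.array([spec.layout[names[j]][2] for j in which])
            d1 = np.array([spec.layout[names[j]][3] for j in which])
            s = rng.uniform(s0, s1)
            d = rng.uniform(d0, d1)

            ell = 1.0 - s  # distal end at the inner terminus
            theta = np.interp(ell * total, grid_l, grid_t)
            theta = theta + rng.uniform(-spec.jitter_theta, spec.jitter_theta,
                                        size=n_cells)
            radius = (
                spec.a
                + spec.b * theta
                + spec.luminal_sign * (d - 0.5) * 2.0 * spec.half_thickness
                + rng.normal(0.0, spec.jitter_r, size=n_cells)
            )
            x = radius * np.cos(theta)
            y = radius * np.sin(theta)
            region = assign_regions(s)
            for i in range(n_cells):
                cid = f"{sample_id}_c{i:06d}"
                cluster = names[which[i]]
                cell_rows.append(
                    {
                        "cell_id": cid,
                        "sample_id": sample_id,
                        "genotype": genotype,
                        "x": x[i],
                        "y": y[i],
                        "cluster": cluster,
                    }
                )
                truth_rows.append(
                    {
                        "cell_id": cid,
                        "s": s[i],
                        "d": d[i],
                        "region": region[i],
                        "cluster": cluster,
                    }
                )
            if spec.with_counts:
                for gene, rates in _COUNT_RATES.items():
                    lam = np.array([rates.get(names[j], 0.02) for j in which])
                    count_rows.append(rng.poisson(lam))
    cells = pd.DataFrame(cell_rows)
    truth = pd.DataFrame(truth_rows).set_index("cell_id")
    if spec.with_counts:
        genes = list(_COUNT_RATES)
        stacked = np.column_stack(
            [np.concatenate(count_rows[i::len(genes)]) for i in range(len(genes))]
        )
        counts = pd.DataFrame(stacked, index=cells["cell_id"], columns=genes)
        return cells, truth, counts
    return cells, truth


# ---------------------------------------------------------------------------
# monoclonal standard curves
# ---------------------------------------------------------------------------


def simulate_standard_curve(
    params: tuple[float, float, float, float] = (0.05, 3.0, 100.0, 1.0),
    concentrations=(1.0, 10.0, 100.0, 1000.0, 10000.0),
    noise_sd: float = 0.0,
    n_replicates: int = 2,
    seed: int = 0,
):
    """Forward-4PL standards table; returns (table, truth params).

    ``params`` is (lower, upper, inflection, hill) of the generating
    curve.
    """
    lower, upper, inflection, hill = params
    if upper == lower:
        # degenerate on purpose: downstream fitting must reject it
        pass
    rng = np.random.default_rng(seed)
    rows = []
    for conc in concentrations:
        od = float(_fourpl(conc, lower, upper, inflection, hill))
        for rep in range(n_replicates):
            rows.append(
                {
                    "concentration": conc,
                    "od": od + (rng.normal(0.0, noise_sd) if noise_sd else 0.0),
                    "replicate": rep,
                }
            )
    return pd.DataFrame(rows), dict(
        lower=lower, upper=upper, inflection=inflection, hill=hill
    )
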