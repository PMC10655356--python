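"""Seeded synthetic-data generators with known ground truth.

Three generators emulate the data families of the study design so that
every pipeline stage can be exercised and validated without any download:

* :func:`generate_dsilac` — peptide-level dynamic-SILAC tables over a
  1/2/4/6-day heavy-medium course, with a log-normal half-life
  distribution (median 4 days) plus explicit long-lived (> 20 days) and
  fast (0.3–2 days) tails;
* :func:`generate_spatial` — protein × sample intensity tables for
  bait-vs-control enrichment designs, with planted enriched proteins,
  per-sample global scale factors (absorbed by reference normalization)
  and an endogenously biotinylated reference protein (PCCA) present in
  every sample;
* :func:`generate_ph` — nigericin-clamp calibration tables plus
  per-lysosome fluorescence objects with per-group pH distributions
  (defaults 4.31 ± 0.16 and 4.81 ± 0.24).

Every generator returns its :class:`SyntheticTruth` (the planted
parameters), and identical (parameters, seed) yield identical tables.
Measurement noise is multiplicative log-normal parameterized by CV, the
standard assumption for MS intensities.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError

LN2 = float(np.log(2.0))


@dataclass
class SyntheticTruth:
    """Planted parameters attached to a generated dataset."""

    dataset_id: str
    seed: int
    params: dict
    true_half_lives: dict | None = None  # group -> {protein_id: days}
    enriched: list[str] = field(default_factory=list)
    depleted: list[str] = field(default_factory=list)
    translocators: dict = field(default_factory=dict)  # protein_id -> direction
    calibration_coefficients: list[float] | None = None
    group_ph_params: dict | None = None  # group -> (mean, sd)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path, "r", encoding="utf-8") as fh:
            return cls(**json.load(fh))


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative log-normal noise with the given CV."""
    if cv <= 0:
        return np.ones(size)
    sigma = float(np.sqrt(np.log1p(cv * cv)))
    return rng.lognormal(mean=-sigma * sigma / 2.0, sigma=sigma, size=size)


# ---------------------------------------------------------------------------
# dynamic SILAC
# ---------------------------------------------------------------------------

@dataclass
class DSilacDesign:
    """Design of a synthetic dynamic-SILAC experiment.

    Defaults follow the study conditions: four sampling times at 1, 2, 4
    and 6 days after the heavy-medium switch, a log-normal half-life
    distribution with median 4 days, a long-lived tail (> 20 days, e.g.
    histones and nucleoporins) and a fast tail (0.3–2 days), 20% CV
    multiplicative measurement noise, and 4 biological replicates.
    """

    n_proteins: int = 500
    peptides_per_protein: int = 5
    n_replicates: int = 4
    timepoints_h: tuple[float, ...] = (24.0, 48.0, 96.0, 144.0)
    halflife_median_days: float = 4.0
    halflife_log_sd: float = 0.6
    long_lived_fraction: float = 0.05
    fast_fraction: float = 0.05
    noise_cv: float = 0.2
    missing_rate: float = 0.0
    replicate_cv: float = 0.0  # biological inter-replicate spread of half-lives
    missed_cleavage_fraction: float = 0.0
    shared_peptide_fraction: float = 0.0
    abundance_median: float = 1e7
    abundance_log_sd: float = 1.0

    def __post_init__(self) -> None:
        for name in ("long_lived_fraction", "fast_fraction", "missing_rate",
                     "missed_cleavage_fraction", "shared_peptide_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]; got {v}")
        if any(t <= 0 for t in self.timepoints_h):
            raise ValidationError("timepoints_h must be positive")
        if self.halflife_median_days <= 0 or self.halflife_log_sd < 0:
            raise ValidationError("invalid half-life distribution parameters")


def _draw_half_lives(design: DSilacDesign, rng: np.random.Generator) -> np.ndarray:
    t = rng.lognormal(mean=np.log(design.halflife_median_days),
                      sigma=design.halflife_log_sd, size=design.n_proteins)
    n_long = int(round(design.long_lived_fraction * design.n_proteins))
    n_fast = int(round(design.fast_fraction * design.n_proteins))
    special = rng.choice(design.n_proteins, size=n_long + n_fast, replace=False)
    t[special[:n_long]] = rng.uniform(20.0, 40.0, size=n_long)
    t[special[n_long:]] = rng.uniform(0.3, 2.0, size=n_fast)
    return t


def generate_dsilac(
    design: DSilacDesign | None = None,
    group_effects: Mapping[str, Mapping[str, float] | float] | None = None,
    seed: int = 0,
    dataset_id: str = "dsilac",
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate a tidy peptide observation table with planted half-lives.

    For a protein with true rate ``k`` and peptide abundance ``a``, the
    expected intensities at time ``t`` are ``light = a·exp(-k t)`` and
    ``heavy = a·(1 - exp(-k t))``, each perturbed by mean-one log-normal
    noise at the design CV, then thinned completely at random at the
    design missing rate.

    ``group_effects`` maps group name to either a scalar half-life
    multiplier applied to every protein or a ``{protein_id: multiplier}``
    map (proteins absent from the map keep multiplier 1). Omitted →
    a single ``WT`` group.
    """
    design = design or DSilacDesign()
    rng = np.random.default_rng(seed)
    protein_ids = [f"P{i:05d}" for i in range(design.n_proteins)]
    gene_symbols = [f"GENE{i}" for i in range(design.n_proteins)]
    base_half = _draw_half_lives(design, rng)
    abundance = rng.lognormal(np.log(design.abundance_median),
                              design.abundance_log_sd, design.n_proteins)
    pep_factors = rng.lognormal(0.0, 0.5,
                                (design.n_proteins, design.peptides_per_protein))
    missed = rng.random((design.n_proteins, design.peptides_per_protein)) \
        < design.missed_cleavage_fraction
    shared = rng.random((design.n_proteins, design.peptides_per_protein)) \
        < design.shared_peptide_fraction

    groups = {"WT": 1.0} if group_effects is None else dict(group_effects)
    truth_half: dict[str, dict[str, float]] = {}
    frames = []
    for group, effect in groups.items():
        if np.isscalar(effect):
            mult = np.full(design.n_proteins, float(effect))
        else:
            mult = np.array([float(effect.get(p, 1.0)) for p in protein_ids])
        half = base_half * mult
        truth_half[group] = dict(zip(protein_ids, half.tolist()))
        k = LN2 / half  # per day
        for rep in range(1, design.n_replicates + 1):
            rep_mult = _lognormal_noise(rng, design.replicate_cv, design.n_proteins)
            k_rep = LN2 / (half * rep_mult)
            for t_h in design.timepoints_h:
                t_d = t_h / 24.0
                light_frac = np.exp(-k_rep * t_d)
                base = abundance[:, None] * pep_factors  # protein × peptide
                light = base * light_frac[:, None]
                heavy = base * (1.0 - light_frac)[:, None]
                light = light * _lognormal_noise(rng, design.noise_cv, base.shape)
                heavy = heavy * _lognormal_noise(rng, design.noise_cv, base.shape)
                n_p, n_pep = base.shape
                frames.append(pd.DataFrame({
                    "peptide_sequence": [f"PEP{i:05d}K{j}" for i in range(n_p)
                                         for j in range(n_pep)],
                    "protein_id": np.repeat(protein_ids, n_pep),
                    "gene_symbol": np.repeat(gene_symbols, n_pep),
                    "sample_id": f"{group}_r{rep}_t{int(t_h)}",
                    "group": group,
                    "replicate": rep,
                    "time_h": float(t_h),
                    "intensity_light": light.ravel(),
                    "intensity_heavy": heavy.ravel(),
                    "missed_cleavages": missed.ravel().astype(int),
                    "is_unique": ~shared.ravel(),
                }))
    table = pd.concat(frames, ignore_index=True)
    if design.missing_rate > 0:
        keep = rng.random(len(table)) >= design.missing_rate
        table = table.loc[keep].reset_index(drop=True)
    truth = SyntheticTruth(
        dataset_id=dataset_id,
        seed=seed,
        params=dataclasses.asdict(design),
        true_half_lives=truth_half,
    )
    return table, truth


# ---------------------------------------------------------------------------
# spatial enrichment
# ---------------------------------------------------------------------------

PROBE_DESIGNS = {
    "lyso_apex": "spatial_control",
    "lyso_ip": "no_probe_control",
    "lyso_bar": "no_probe_control",
}


def generate_spatial(
    n_proteins: int = 2000,
    n_planted: int = 150,
    planted_fold: float = 4.0,
    n_translocators: int = 0,
    translocator_fold: float = 3.0,
    probe_design: str = "lyso_apex",
    n_replicates: int = 4,
    cv: float = 0.2,
    reference_protein: str = "PCCA",
    sample_scale_sd: float = 0.3,
    seed: int = 0,
    dataset_id: str = "spatial",
) -> tuple["ProteinIntensityTable", SyntheticTruth]:
    """Generate a protein intensity table for an enrichment design.

    With ``n_translocators == 0`` (default) the samples are ``bait``
    (probe ``lyso_bait``) vs ``control`` (the design's control probe), with
    ``n_planted`` proteins multiplied by ``planted_fold`` in the bait
    samples. With ``n_translocators > 0`` a paired-probe knockout design is
    generated instead: groups ``WT``/``KO`` for both the lysosome bait and
    the spatial-control probe, where translocating proteins gain
    ``translocator_fold`` in the KO lysosome samples while losing it in the
    KO cytosol samples (direction ``to_lysosome``; the mirror image for
    ``from_lysosome``).

    Every sample receives a global log-normal scale factor (SD
    ``sample_scale_sd`` on the log scale) that also multiplies the
    reference protein, so reference normalization removes it exactly.
    """
    from .io import ProteinIntensityTable  # deferred to avoid cycle

    if probe_design not in PROBE_DESIGNS:
        raise ValidationError(f"unknown probe design {probe_design!r}")
    if n_planted + n_translocators >= n_proteins:
        raise ValidationError("planted counts must be smaller than n_proteins")
    rng = np.random.default_rng(seed)
    protein_ids = [f"P{i:05d}" for i in range(n_proteins)]
    if reference_protein in protein_ids:
        raise ValidationError("reference protein collides with generated accessions")
    gene_symbols = pd.Series([f"GENE{i}" for i in range(n_proteins)] + [reference_protein],
                             index=protein_ids + [reference_protein])
    chosen = rng.choice(n_proteins, size=n_planted + n_translocators, replace=False)
    planted = [protein_ids[i] for i in chosen[:n_planted]]
    translocators = [protein_ids[i] for i in chosen[n_planted:]]
    base = rng.lognormal(np.log(1e7), 1.0, n_proteins)
    ref_abundance = 5e8  # most abundant endogenously biotinylated protein

    planted_mask = np.zeros(n_proteins, dtype=bool)
    planted_mask[chosen[:n_planted]] = True
    to_lyso_mask = np.zeros(n_proteins, dtype=bool)
    from_lyso_mask = np.zeros(n_proteins, dtype=bool)
    half = n_translocators // 2
    to_lyso_mask[chosen[n_planted:n_planted + half]] = True
    from_lyso_mask[chosen[n_planted + half:n_planted + n_translocators]] = True

    columns: dict[str, np.ndarray] = {}
    samples_rows = []

    def add_sample(name: str, group: str, probe: str, replicate: int,
                   mean_vec: np.ndarray) -> None:
        scale = float(rng.lognormal(0.0, sample_scale_sd))
        noisy = mean_vec * _lognormal_noise(rng, cv, n_proteins) * scale
        # the reference tracks the per-sample scale factor exactly, so
        # normalizing to it removes the scale without adding noise
        ref = ref_abundance * scale
        columns[name] = np.concatenate([noisy, [ref]])
        samples_rows.append({"sample_id": name, "group": group,
                             "probe": probe, "replicate": replicate})

    if n_translocators == 0:
        control_probe = PROBE_DESIGNS[probe_design]
        bait_mean = np.where(planted_mask, base * planted_fold, base)
        for rep in range(1, n_replicates + 1):
            add_sample(f"bait_r{rep}", "bait", "lyso_bait", rep, bait_mean)
        for rep in range(1, n_replicates + 1):
            add_sample(f"control_r{rep}", "control", control_probe, rep, base)
    else:
        lyso_wt = np.where(planted_mask, base * planted_fold, base)
        lyso_ko = lyso_wt * np.where(to_lyso_mask, translocator_fold, 1.0) \
            / np.where(from_lyso_mask, translocator_fold, 1.0)
        cyto_wt = base
        cyto_ko = cyto_wt / np.where(to_lyso_mask, translocator_fold, 1.0) \
            * np.where(from_lyso_mask, translocator_fold, 1.0)
        for rep in range(1, n_replicates + 1):
            add_sample(f"WT_lyso_r{rep}", "WT", "lyso_bait", rep, lyso_wt)
        for rep in range(1, n_replicates + 1):
            add_sample(f"KO_lyso_r{rep}", "KO", "lyso_bait", rep, lyso_ko)
        for rep in range(1, n_replicates + 1):
            add_sample(f"WT_cyto_r{rep}", "WT", "spatial_control", rep, cyto_wt)
        for rep in range(1, n_replicates + 1):
            add_sample(f"KO_cyto_r{rep}", "KO", "spatial_control", rep, cyto_ko)

    intens = pd.DataFrame(columns, index=protein_ids + [reference_protein])
    samples = pd.DataFrame(samples_rows).set_index("sample_id")
    table = ProteinIntensityTable(intens, samples, gene_symbols)
    truth = SyntheticTruth(
        dataset_id=dataset_id,
        seed=seed,
        params={
            "n_proteins": n_proteins, "n_planted": n_planted,
            "planted_fold": planted_fold, "n_translocators": n_translocators,
            "translocator_fold": translocator_fold, "probe_design": probe_design,
            "n_replicates": n_replicates, "cv": cv,
            "reference_protein": reference_protein,
            "sample_scale_sd": sample_scale_sd,
        },
        enriched=sorted(planted),
        translocators={
            **{protein_ids[i]: "to_lysosome" for i in np.flatnonzero(to_lyso_mask)},
            **{protein_ids[i]: "from_lysosome" for i in np.flatnonzero(from_lyso_mask)},
        },
    )
    return table, truth


# ---------------------------------------------------------------------------
# lysosomal pH
# ---------------------------------------------------------------------------

DEFAULT_PH_CURVE = (-1.1, 0.4)  # ratio = -1.1 + 0.4*pH, increasing on [4, 8]
DEFAULT_GROUP_PH = {"WT": (4.31, 0.16), "GRN_KO": (4.81, 0.24)}


def generate_ph(
    true_coefficients: tuple[float, ...] = DEFAULT_PH_CURVE,
    buffer_phs: tuple[float, ...] = (4.0, 5.0, 6.0, 7.0, 8.0),
    group_ph_params: Mapping[str, tuple[float, float]] | None = None,
    wells_per_group: int = 15,
    objects_per_well: int = 100,
    calibration_noise_cv: float = 0.01,
    ratio_noise_cv: float = 0.03,
    i555_mean: float = 1000.0,
    seed: int = 0,
    dataset_id: str = "ph",
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate a calibration table and per-lysosome fluorescence objects.

    The true curve (polynomial coefficients in increasing degree, strictly
    monotone over pH 4–8) maps pH to the 488/555 ratio. Calibration ratios
    are the curve at the buffer pHs with ``calibration_noise_cv``
    multiplicative noise. Per-object pH is drawn from the group's normal
    distribution (defaults: WT 4.31 ± 0.16, GRN_KO 4.81 ± 0.24), passed
    through the true curve, and split into two channels with
    ``ratio_noise_cv`` noise on the 488 channel.

    Returns ``(calibration, objects, truth)``.
    """
    coef = np.asarray(true_coefficients, dtype=float)
    grid = np.linspace(4.0, 8.0, 401)
    vals = np.polynomial.polynomial.polyval(grid, coef)
    d = np.diff(vals)
    if not ((d > 0).all() or (d < 0).all()):
        raise ValidationError("supplied true curve is not strictly monotone on [4, 8]")
    if (vals <= 0).any():
        raise ValidationError("true curve must yield positive ratios on [4, 8]")
    group_ph_params = dict(group_ph_params or DEFAULT_GROUP_PH)
    rng = np.random.default_rng(seed)

    calib = pd.DataFrame({
        "buffer_pH": list(buffer_phs),
        "mean_ratio": np.polynomial.polynomial.polyval(np.asarray(buffer_phs), coef)
        * _lognormal_noise(rng, calibration_noise_cv, len(buffer_phs)),
    })

    rows = []
    for group, (mu, sd) in group_ph_params.items():
        for w in range(1, wells_per_group + 1):
            ph = rng.normal(mu, sd, objects_per_well)
            ph = np.clip(ph, 4.0, 8.0)  # stay inside the calibration range
            ratio = np.polynomial.polynomial.polyval(ph, coef)
            i555 = i555_mean * _lognormal_noise(rng, 0.2, objects_per_well)
            i488 = ratio * i555 * _lognormal_noise(rng, ratio_noise_cv, objects_per_well)
            rows.append(pd.DataFrame({
                "object_id": [f"{group}_w{w:02d}_obj{i:04d}"
                              for i in range(objects_per_well)],
                "well_id": f"{group}_w{w:02d}",
                "group": group,
                "i488": i488,
                "i555": i555,
                "true_pH": ph,
            }))
    objects = pd.concat(rows, ignore_index=True)
    truth = SyntheticTruth(
        dataset_id=dataset_id,
        seed=seed,
        params={
            "buffer_phs": list(buffer_phs),
            "wells_per_group": wells_per_group,
            "objects_per_well": objects_per_well,
            "calibration_noise_cv": calibration_noise_cv,
            "ratio_noise_cv": ratio_noise_cv,
        },
        calibration_coefficients=[float(c) for c in coef],
        group_ph_params={g: list(p) for g, p in group_ph_params.items()},
    )
    return calib, objects, truth
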