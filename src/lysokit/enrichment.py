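"""Organelle-enrichment statistics for proximity-labeling and organelle-IP designs.

The shared workflow for Lyso-APEX (with a cytosolic spatial control),
Lyso-IP (no-probe control only) and Lyso-BAR (no-primary-antibody control)
proteomics:

1. normalize every sample to an endogenously biotinylated reference protein
   (PCCA by default), which absorbs per-sample loading/labeling scale;
2. per-protein bait-vs-control differential tests — log2 of the group-mean
   ratio, Welch t-tests on log2-normalized intensities, BH correction;
3. the volcano gates of the study design: adjusted p < alpha (0.05) and a
   linear 1.5-fold ratio gate;
4. spatial-control filtering (remove cytosolic and nonspecific labeling)
   and translocation calls from paired lysosome/cytosol probes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import RunConfig
from .differential import bh_adjust
from .errors import AlignmentError, DesignError, InsufficientDataError, NormalizationError, ValidationError
from .io import ProteinIntensityTable


def normalize_to_reference(table: ProteinIntensityTable,
                           reference: str = "PCCA") -> ProteinIntensityTable:
    """Divide each sample by its reference-protein intensity.

    After normalization the reference row equals 1 in every sample; the
    operation is idempotent and removes any per-sample global scale factor.
    Raises :class:`NormalizationError` naming the offending sample if the
    reference is missing, zero, or NaN anywhere.
    """
    if reference not in table.intensities.index:
        raise NormalizationError(f"reference protein {reference!r} absent from the table")
    ref = table.intensities.loc[reference]
    bad = ref.index[~(ref > 0)]
    if len(bad):
        raise NormalizationError(
            f"reference protein {reference!r} missing or non-positive in sample(s): {list(bad)}"
        )
    return table.copy_with(table.intensities.div(ref, axis=1))


class EnrichmentModel:
    """Bait-vs-control differential enrichment on a protein intensity table.

    Parameters
    ----------
    table : ProteinIntensityTable
        Raw protein × sample intensities with sample group/probe labels.
    config : RunConfig
        Gates (alpha, ratio_gate), reference protein, replicate minimum.
    normalize : bool
        Apply reference normalization before testing (default True).
    """

    def __init__(self, table: ProteinIntensityTable, config: RunConfig | None = None,
                 normalize: bool = True) -> None:
        self.config = config or RunConfig()
        self.raw = table
        self.table = (
            normalize_to_reference(table, self.config.reference_protein) if normalize else table
        )

    def select_samples(self, group: str | None = None, probe: str | None = None) -> list[str]:
        return self.table.select_samples(group=group, probe=probe)

    def fit(self, samples_a: Sequence[str], samples_b: Sequence[str],
            label: str = "") -> "EnrichmentResults":
        """Differential enrichment of sample set A over sample set B.

        ``log2_ratio`` is log2(mean_A / mean_B) of normalized intensities;
        p-values come from Welch t-tests on log2 intensities; BH correction
        runs across the proteins tested. Proteins with fewer than
        ``min_replicates_quantified`` finite values in either set are
        excluded and counted.
        """
        samples_a, samples_b = list(samples_a), list(samples_b)
        if len(samples_a) < 2 or len(samples_b) < 2:
            raise DesignError("each side of the contrast needs >= 2 samples")
        cfg = self.config
        A = self.table.intensities[samples_a].to_numpy(dtype=float)
        B = self.table.intensities[samples_b].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            la = np.where(A > 0, np.log2(A), np.nan)
            lb = np.where(B > 0, np.log2(B), np.nan)
        n_a = np.isfinite(la).sum(axis=1)
        n_b = np.isfinite(lb).sum(axis=1)
        testable = (n_a >= cfg.min_replicates_quantified) & (n_b >= cfg.min_replicates_quantified)
        n_excluded = int((~testable).sum())
        idx = self.table.intensities.index[testable]
        if len(idx) == 0:
            raise InsufficientDataError("no protein passes the replicate minimum")
        la, lb = la[testable], lb[testable]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            tt = stats.ttest_ind(la, lb, axis=1, equal_var=False, nan_policy="omit")
        p_raw = np.where(np.isnan(np.asarray(tt.pvalue, dtype=float)), 1.0,
                         np.asarray(tt.pvalue, dtype=float))
        mean_a = np.nanmean(np.where(np.isfinite(la), 2.0 ** la, np.nan), axis=1)
        mean_b = np.nanmean(np.where(np.isfinite(lb), 2.0 ** lb, np.nan), axis=1)
        log2_ratio = np.log2(mean_a / mean_b)

        t = pd.DataFrame({
            "protein_id": idx,
            "gene_symbol": self.table.gene_symbols.loc[idx].to_numpy(),
            "log2_ratio": log2_ratio,
            "p_raw": p_raw,
            "n_a": n_a[testable],
            "n_b": n_b[testable],
        }).sort_values("protein_id", kind="stable").reset_index(drop=True)
        t["q_bh"] = bh_adjust(t["p_raw"].to_numpy())
        gate = np.log2(cfg.ratio_gate)
        t["passes_p"] = t["q_bh"] < cfg.alpha
        t["passes_ratio"] = t["log2_ratio"].abs() >= gate
        t["enriched"] = t["passes_p"] & (t["log2_ratio"] >= gate)
        t["depleted"] = t["passes_p"] & (t["log2_ratio"] <= -gate)
        return EnrichmentResults(self, t, n_excluded, label or "A_vs_B")


class EnrichmentResults:
    """Volcano-ready per-protein enrichment statistics for one contrast."""

    def __init__(self, model: EnrichmentModel, table: pd.DataFrame,
                 n_excluded: int, label: str) -> None:
        self.model = model
        self.table = table
        self.n_excluded = n_excluded
        self.label = label

    @property
    def alpha(self) -> float:
        return self.model.config.alpha

    def enriched_set(self) -> set[str]:
        return set(self.table.loc[self.table["enriched"], "protein_id"])

    def depleted_set(self) -> set[str]:
        return set(self.table.loc[self.table["depleted"], "protein_id"])

    def universe(self) -> set[str]:
        return set(self.table["protein_id"])

    def volcano_table(self) -> pd.DataFrame:
        t = self.table.copy()
        with np.errstate(divide="ignore"):
            t["neg_log10_q"] = -np.log10(t["q_bh"])
        return t

    def summary(self) -> str:
        cfg = self.model.config
        return (
            f"Enrichment contrast: {self.label}\n"
            f"  proteins tested:  {len(self.table)} (excluded: {self.n_excluded})\n"
            f"  gates:            q < {cfg.alpha:g}, ratio >= {cfg.ratio_gate:g}\n"
            f"  enriched:         {int(self.table['enriched'].sum())}\n"
            f"  depleted:         {int(self.table['depleted'].sum())}"
        )


@dataclass
class SpatialFilterReport:
    """Outcome of spatial-control / nonspecific filtering.

    ``retained`` ∪ ``removed_cytosolic`` ∪ ``removed_nonspecific`` equals the
    tested universe; the three sets are disjoint.
    """

    retained: set[str]
    removed_cytosolic: set[str]
    removed_nonspecific: set[str]

    def summary(self) -> str:
        return (
            "Spatial filter report\n"
            f"  retained:            {len(self.retained)}\n"
            f"  removed (cytosolic): {len(self.removed_cytosolic)}\n"
            f"  removed (nonspecific): {len(self.removed_nonspecific)}"
        )


def spatial_filter(bait_vs_noprobe: EnrichmentResults,
                   bait_vs_spatialcontrol: EnrichmentResults | None = None) -> SpatialFilterReport:
    """Keep proteins enriched against the no-probe control and, when a
    spatial (cytosolic) control exists, also enriched against it.

    Proteins failing the no-probe comparison are ``removed_nonspecific``;
    proteins passing it but flat against the spatial control are
    ``removed_cytosolic``. In organelle-IP mode (no spatial control) only
    the nonspecific filter applies.
    """
    universe = bait_vs_noprobe.universe()
    if bait_vs_spatialcontrol is not None:
        shared = universe & bait_vs_spatialcontrol.universe()
        if not shared:
            raise AlignmentError("enrichment results share no proteins")
        universe = shared
    specific = bait_vs_noprobe.enriched_set() & universe
    removed_nonspecific = universe - specific
    if bait_vs_spatialcontrol is None:
        return SpatialFilterReport(specific, set(), removed_nonspecific)
    spatial_ok = bait_vs_spatialcontrol.enriched_set() & universe
    retained = specific & spatial_ok
    removed_cytosolic = specific - spatial_ok
    return SpatialFilterReport(retained, removed_cytosolic, removed_nonspecific)


def translocation_calls(lyso: EnrichmentResults, cytosol: EnrichmentResults,
                        alpha: float | None = None) -> pd.DataFrame:
    """Call proteins that move between lysosome surface and cytosol.

    A protein is called ``to_lysosome`` when it is significantly increased
    (q < alpha) in the lysosome probe comparison while significantly
    decreased in the cytosolic probe comparison; ``from_lysosome`` is the
    mirror image. Same-direction or single-probe changes are not called.
    """
    alpha = lyso.alpha if alpha is None else float(alpha)
    a = lyso.table.set_index("protein_id")
    b = cytosol.table.set_index("protein_id")
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise AlignmentError("lysosome and cytosol results share no proteins")
    la = a.loc[shared]
    cb = b.loc[shared]
    sig = (la["q_bh"] < alpha) & (cb["q_bh"] < alpha)
    to_lyso = sig & (la["log2_ratio"] > 0) & (cb["log2_ratio"] < 0)
    from_lyso = sig & (la["log2_ratio"] < 0) & (cb["log2_ratio"] > 0)
    called = to_lyso | from_lyso
    out = pd.DataFrame({
        "protein_id": shared[called],
        "direction": np.where(to_lyso[called], "to_lysosome", "from_lysosome"),
        "lyso_log2_ratio": la.loc[called, "log2_ratio"].to_numpy(),
        "cytosol_log2_ratio": cb.loc[called, "log2_ratio"].to_numpy(),
        "both_significant": True,
    }).reset_index(drop=True)
    return out


def probe_overlap(enriched_sets: Mapping[str, set[str]]) -> dict:
    """Pairwise and full-intersection counts across probe enrichment sets.

    Input order is preserved in the output; counts are exact set algebra
    (the numbers behind a Venn diagram).
    """
    names = list(enriched_sets)
    if len(names) < 2:
        raise ValidationError("probe_overlap needs >= 2 named sets")
    sets = {n: set(s) for n, s in enriched_sets.items()}
    out: dict = {
        "sizes": {n: len(sets[n]) for n in names},
        "pairwise_intersections": {},
        "pairwise_unique": {},
    }
    for i, n1 in enumerate(names):
        for n2 in names[i + 1:]:
            key = f"{n1}&{n2}"
            out["pairwise_intersections"][key] = len(sets[n1] & sets[n2])
            out["pairwise_unique"][key] = (len(sets[n1] - sets[n2]), len(sets[n2] - sets[n1]))
    full = set.intersection(*sets.values())
    out["full_intersection"] = len(full)
    out["union"] = len(set.union(*sets.values()))
    return out
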