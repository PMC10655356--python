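"""Readers and writers for the three table families, and contaminant filtering.

Three kinds of input are consumed:

* peptide-level quantification tables (TSV in a MaxQuant-evidence-like
  dialect) for the dynamic-SILAC turnover workflow;
* protein-by-sample intensity tables plus a sample-metadata table for the
  organelle-enrichment workflows (Lyso-APEX / Lyso-IP / Lyso-BAR designs);
* per-lysosome fluorescence tables (CSV) plus a pH calibration table for the
  ratiometric pH workflow.

All tables are plain UTF-8 TSV/CSV with a decimal point; missing intensities
are encoded as absent (an empty cell or a dropped row), never as zero — a
zero intensity is a measured zero and behaves differently in ratio
computation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import EmptyInputError, FormatError, ValidationError

logger = logging.getLogger(__name__)

#: Default column-name map for peptide tables (MaxQuant evidence dialect).
DEFAULT_PEPTIDE_COLUMNS: dict[str, str] = {
    "peptide_sequence": "Sequence",
    "protein_id": "Leading razor protein",
    "gene_symbol": "Gene names",
    "sample_id": "Experiment",
    "intensity_light": "Intensity L",
    "intensity_heavy": "Intensity H",
    "missed_cleavages": "Missed cleavages",
}

PEPTIDE_FIELDS = [
    "peptide_sequence",
    "protein_id",
    "gene_symbol",
    "sample_id",
    "group",
    "replicate",
    "time_h",
    "intensity_light",
    "intensity_heavy",
    "missed_cleavages",
    "is_unique",
]


def read_peptide_table(
    path: str | Path,
    metadata: Mapping[str, tuple[str, int, float]] | pd.DataFrame,
    column_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a peptide-level quantification TSV into a tidy observation table.

    Parameters
    ----------
    path : path
        Tab-separated file with at least the columns named in ``column_map``
        (MaxQuant evidence dialect by default).
    metadata : mapping or DataFrame
        Maps each ``sample_id`` to its ``(group, replicate, time_h)``; as a
        DataFrame it must carry columns ``sample_id, group, replicate, time_h``.
    column_map : mapping, optional
        Overrides for the file's column names, keyed by canonical field name.

    Returns
    -------
    DataFrame with one row per (peptide, sample) and the canonical columns
    ``peptide_sequence, protein_id, gene_symbol, sample_id, group, replicate,
    time_h, intensity_light, intensity_heavy, missed_cleavages, is_unique``.
    Rows whose intensity cells are blank or non-numeric are dropped; the drop
    count is logged at INFO.
    """
    cols = dict(DEFAULT_PEPTIDE_COLUMNS)
    if column_map:
        cols.update(column_map)
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if raw.empty:
        raise EmptyInputError(f"peptide table {path} contains no rows")
    required = ["peptide_sequence", "protein_id", "sample_id", "intensity_light", "intensity_heavy"]
    for key in required:
        if cols[key] not in raw.columns:
            raise FormatError(
                f"peptide table {path} lacks required column {cols[key]!r} (field {key})"
            )

    df = pd.DataFrame({
        "peptide_sequence": raw[cols["peptide_sequence"]].str.strip().str.upper(),
        "protein_id": raw[cols["protein_id"]].str.strip(),
        "gene_symbol": raw[cols["gene_symbol"]].str.strip()
        if cols["gene_symbol"] in raw.columns
        else "",
        "sample_id": raw[cols["sample_id"]].str.strip(),
    })
    light = pd.to_numeric(raw[cols["intensity_light"]], errors="coerce")
    heavy = pd.to_numeric(raw[cols["intensity_heavy"]], errors="coerce")
    df["intensity_light"] = light
    df["intensity_heavy"] = heavy
    if cols["missed_cleavages"] in raw.columns:
        df["missed_cleavages"] = (
            pd.to_numeric(raw[cols["missed_cleavages"]], errors="coerce").fillna(0).astype(int)
        )
    else:
        df["missed_cleavages"] = 0
    if "is_unique" in raw.columns:
        df["is_unique"] = raw["is_unique"].str.lower().isin({"true", "1", "yes"})
    else:
        # a peptide mapping to a single leading protein is treated as unique
        df["is_unique"] = True

    bad = light.isna() | heavy.isna()
    n_dropped = int(bad.sum())
    if n_dropped:
        logger.info("read_peptide_table: dropped %d rows with non-numeric intensities", n_dropped)
        for idx in df.index[bad]:
            logger.debug("dropped row %d: unparseable intensity", idx)
    df = df.loc[~bad].reset_index(drop=True)
    if (df["intensity_light"] < 0).any() or (df["intensity_heavy"] < 0).any():
        raise ValidationError("negative intensities are not permitted")
    if (df["peptide_sequence"] == "").any():
        raise FormatError("empty peptide sequence encountered")

    meta = _coerce_sample_metadata(metadata)
    unknown = set(df["sample_id"]) - set(meta.index)
    if unknown:
        raise FormatError(f"samples without metadata: {sorted(unknown)}")
    df["group"] = df["sample_id"].map(meta["group"])
    df["replicate"] = df["sample_id"].map(meta["replicate"]).astype(int)
    df["time_h"] = df["sample_id"].map(meta["time_h"]).astype(float)
    if (df["time_h"] <= 0).any():
        raise ValidationError("time_h must be positive")
    df.attrs["n_dropped_rows"] = n_dropped
    return df[PEPTIDE_FIELDS]


def _coerce_sample_metadata(metadata) -> pd.DataFrame:
    if isinstance(metadata, pd.DataFrame):
        meta = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata
        missing = {"group", "replicate", "time_h"} - set(meta.columns)
        if missing:
            raise FormatError(f"sample metadata lacks columns: {sorted(missing)}")
        return meta[["group", "replicate", "time_h"]]
    rows = {
        sid: {"group": g, "replicate": r, "time_h": t} for sid, (g, r, t) in metadata.items()
    }
    return pd.DataFrame.from_dict(rows, orient="index")


def write_peptide_table(df: pd.DataFrame, path: str | Path,
                        column_map: Mapping[str, str] | None = None) -> None:
    """Write a tidy peptide table back to the MaxQuant-evidence-like dialect."""
    cols = dict(DEFAULT_PEPTIDE_COLUMNS)
    if column_map:
        cols.update(column_map)
    out = pd.DataFrame({
        cols["peptide_sequence"]: df["peptide_sequence"],
        cols["protein_id"]: df["protein_id"],
        cols["gene_symbol"]: df["gene_symbol"],
        cols["sample_id"]: df["sample_id"],
        cols["intensity_light"]: df["intensity_light"],
        cols["intensity_heavy"]: df["intensity_heavy"],
        cols["missed_cleavages"]: df["missed_cleavages"],
        "is_unique": df["is_unique"],
    })
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def sample_metadata_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Extract the sample→(group, replicate, time_h) table from a peptide table."""
    return (
        df[["sample_id", "group", "replicate", "time_h"]]
        .drop_duplicates("sample_id")
        .reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# Protein-by-sample intensity tables (enrichment workflows)
# ---------------------------------------------------------------------------

PROBE_LABELS = ("lyso_bait", "spatial_control", "no_probe_control")


@dataclass
class ProteinIntensityTable:
    """Protein × sample intensity matrix with sample annotations.

    ``intensities`` is indexed by protein accession with one column per
    sample; missing values are NaN (never zero). ``samples`` is indexed by
    sample id and carries ``group``, ``probe`` and ``replicate`` columns;
    the probe label is one of ``lyso_bait``, ``spatial_control``,
    ``no_probe_control``.
    """

    intensities: pd.DataFrame
    samples: pd.DataFrame
    gene_symbols: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.gene_symbols is None:
            self.gene_symbols = pd.Series("", index=self.intensities.index)
        if list(self.intensities.columns) != list(self.samples.index):
            missing = set(self.intensities.columns) ^ set(self.samples.index)
            if missing:
                raise FormatError(f"sample mismatch between matrix and metadata: {sorted(missing)}")
            self.samples = self.samples.loc[self.intensities.columns]
        for col in ("group", "probe"):
            if col not in self.samples.columns:
                raise FormatError(f"sample metadata lacks a {col!r} column")
        if (self.intensities.to_numpy(dtype=float) < 0).any():
            raise ValidationError("protein intensities must be non-negative")
        if not self.gene_symbols.index.equals(self.intensities.index):
            raise FormatError("gene_symbols index must match the protein index")

    @property
    def protein_ids(self) -> pd.Index:
        return self.intensities.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.intensities.columns

    def select_samples(self, group: str | None = None, probe: str | None = None) -> list[str]:
        mask = pd.Series(True, index=self.samples.index)
        if group is not None:
            mask &= self.samples["group"] == group
        if probe is not None:
            mask &= self.samples["probe"] == probe
        return list(self.samples.index[mask])

    def copy_with(self, intensities: pd.DataFrame) -> "ProteinIntensityTable":
        return ProteinIntensityTable(intensities, self.samples.copy(),
                                     self.gene_symbols.loc[intensities.index].copy())


def read_protein_table(matrix_path: str | Path, samples_path: str | Path) -> ProteinIntensityTable:
    """Read a protein × sample TSV plus its sample-metadata TSV.

    The matrix file has columns ``protein_id, gene_symbol, <sample...>``;
    the metadata file has columns ``sample_id, group, probe, replicate``.
    """
    mat = pd.read_csv(matrix_path, sep="\t")
    if mat.empty:
        raise EmptyInputError(f"protein table {matrix_path} contains no rows")
    if "protein_id" not in mat.columns:
        raise FormatError("protein table lacks required column 'protein_id'")
    meta = pd.read_csv(samples_path, sep="\t")
    for col in ("sample_id", "group", "probe"):
        if col not in meta.columns:
            raise FormatError(f"sample metadata lacks required column {col!r}")
    meta = meta.set_index("sample_id")
    gene = mat["gene_symbol"] if "gene_symbol" in mat.columns else pd.Series("", index=mat.index)
    sample_cols = [c for c in mat.columns if c not in ("protein_id", "gene_symbol")]
    intens = mat[sample_cols].astype(float)
    intens.index = mat["protein_id"]
    gene.index = mat["protein_id"]
    return ProteinIntensityTable(intens, meta.loc[sample_cols], gene)


def write_protein_table(table: ProteinIntensityTable, matrix_path: str | Path,
                        samples_path: str | Path) -> None:
    out = table.intensities.copy()
    out.insert(0, "gene_symbol", table.gene_symbols)
    out.insert(0, "protein_id", table.intensities.index)
    out.to_csv(matrix_path, sep="\t", index=False, float_format="%.10g")
    table.samples.reset_index(names="sample_id").to_csv(samples_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Fluorescence / calibration tables (pH workflow)
# ---------------------------------------------------------------------------

def read_fluorescence_table(path: str | Path) -> pd.DataFrame:
    """Read a per-lysosome fluorescence CSV.

    Requires columns ``object_id, well_id, group, i488, i555``; optional
    ``background_488``/``background_555`` columns enable background
    subtraction downstream. The 555 nm loading-control channel must be
    strictly positive so the 488/555 ratio is defined.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise EmptyInputError(f"fluorescence table {path} contains no rows")
    required = {"object_id", "well_id", "group", "i488", "i555"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"fluorescence table lacks columns: {sorted(missing)}")
    if (df["i555"] <= 0).any():
        raise ValidationError("i555 (loading-control channel) must be > 0 for every object")
    if (df["i488"] < 0).any():
        raise ValidationError("i488 must be non-negative")
    return df


def read_calibration_table(path: str | Path) -> pd.DataFrame:
    """Read a calibration CSV with columns ``buffer_pH, mean_ratio``."""
    df = pd.read_csv(path)
    missing = {"buffer_pH", "mean_ratio"} - set(df.columns)
    if missing:
        raise FormatError(f"calibration table lacks columns: {sorted(missing)}")
    if (df["mean_ratio"] <= 0).any():
        raise ValidationError("calibration ratios must be positive")
    return df


# ---------------------------------------------------------------------------
# Contaminant filtering
# ---------------------------------------------------------------------------

@dataclass
class ContaminantReport:
    removed_ids: list[str]
    n_removed: int
    n_retained: int


def read_contaminant_list(path: str | Path) -> set[str]:
    """Read a plain-text accession list (one per line, '#' comments)."""
    out: set[str] = set()
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            token = line.strip()
            if token and not token.startswith("#"):
                out.add(token)
    return out


def remove_contaminants(
    table: pd.DataFrame | ProteinIntensityTable,
    contaminants: Iterable[str],
) -> tuple[pd.DataFrame | ProteinIntensityTable, ContaminantReport]:
    """Drop rows whose protein accession is in the contaminant set.

    Works on any DataFrame with a ``protein_id`` column or protein-indexed
    rows, and on :class:`ProteinIntensityTable`. Idempotent; an empty
    contaminant set is a no-op. If every protein is removed the (empty)
    result is returned with a logged warning so downstream empty-input
    handling can engage.
    """
    cset = set(contaminants)
    if isinstance(table, ProteinIntensityTable):
        keep = ~table.intensities.index.isin(cset)
        removed = sorted(table.intensities.index[~keep].unique())
        filtered: pd.DataFrame | ProteinIntensityTable = table.copy_with(table.intensities.loc[keep])
        n_retained = int(keep.sum())
    else:
        ids = table["protein_id"] if "protein_id" in table.columns else pd.Series(table.index, index=table.index)
        keep = ~ids.isin(cset)
        removed = sorted(ids[~keep].unique())
        filtered = table.loc[keep].reset_index(drop=True) if "protein_id" in table.columns else table.loc[keep]
        n_retained = int(keep.sum())
    report = ContaminantReport(removed_ids=list(removed), n_removed=len(removed), n_retained=n_retained)
    if report.n_removed:
        logger.info("remove_contaminants: removed %d contaminant proteins", report.n_removed)
    if n_retained == 0:
        logger.warning("remove_contaminants: all proteins removed; downstream steps will see an empty table")
    return filtered, report
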