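"""Peak-table data model, I/O, normalization, QC evaluation, missing-value policy.

The peak table is the lingua franca of the pipeline: a samples × metabolites
matrix of non-negative MS responses, carried as a pandas DataFrame whose index
is the sample ids and whose columns are the metabolite ids.  Sample metadata
(patient pairing, tissue type, tissue weight, TNM stage, clinical indices) and
metabolite annotations (chemical class, internal-standard assignment) travel
alongside as lists of records.

Normalization divides each response by the matched internal-standard response
in the same sample and by the sample's tissue weight; pooled-QC samples have
no tissue weight and are normalized by internal standard only.  The division
makes downstream ratios and rank statistics invariant to per-sample
instrument-response scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TISSUE_TYPES = ("tumor", "adjacent", "QC")
TNM_STAGES = ("I", "II", "III", "IV", "none")
CHEMICAL_CLASSES = (
    "FFA",
    "carnitine",
    "OH-carnitine",
    "PC",
    "LPC",
    "SM",
    "amino_acid",
    "nucleoside",
    "other",
)


@dataclass
class SampleRecord:
    """One measured sample: a tissue specimen or a pooled-QC injection."""

    sample_id: str
    patient_id: str
    tissue_type: str  # tumor | adjacent | QC
    tissue_weight: float | None = None  # mg; absent for QC
    tnm_stage: str = "none"  # I | II | III | IV | none
    clinical_indices: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tissue_type not in TISSUE_TYPES:
            raise ValueError(
                f"sample {self.sample_id!r}: tissue_type {self.tissue_type!r} "
                f"not in {TISSUE_TYPES}"
            )
        if self.tnm_stage not in TNM_STAGES:
            raise ValueError(
                f"sample {self.sample_id!r}: tnm_stage {self.tnm_stage!r} "
                f"not in {TNM_STAGES}"
            )
        if self.tissue_type == "QC":
            if self.tnm_stage != "none":
                raise ValueError(f"QC sample {self.sample_id!r} has a TNM stage")
        else:
            if self.tissue_weight is not None and not self.tissue_weight > 0:
                raise ValueError(
                    f"sample {self.sample_id!r}: tissue_weight must be > 0, "
                    f"got {self.tissue_weight}"
                )

    @property
    def is_qc(self) -> bool:
        return self.tissue_type == "QC"


@dataclass
class MetaboliteRecord:
    """Annotation for one measured metabolite."""

    metabolite_id: str
    display_name: str = ""
    chemical_class: str = "other"
    internal_standard_id: str | None = None
    ionization_mode: str = "ESI+"

    def __post_init__(self) -> None:
        if not self.display_name:
            self.display_name = self.metabolite_id
        if self.chemical_class not in CHEMICAL_CLASSES:
            raise ValueError(
                f"metabolite {self.metabolite_id!r}: chemical_class "
                f"{self.chemical_class!r} not in {CHEMICAL_CLASSES}"
            )


class PeakTable:
    """Samples × metabolites intensity matrix with a normalization flag.

    Missing values are NaN.  A table remembers whether it has been normalized
    so that double normalization is rejected.
    """

    def __init__(self, data: pd.DataFrame, normalized: bool = False):
        if data.index.has_duplicates:
            dup = data.index[data.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dup}")
        if data.columns.has_duplicates:
            dup = data.columns[data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate metabolite ids: {dup}")
        values = data.to_numpy()
        if np.isinf(values).any():
            raise ValueError("peak table contains non-finite (inf) intensities")
        if not normalized:  # raw MS responses cannot be negative
            with np.errstate(invalid="ignore"):
                if (values < 0).any():
                    raise ValueError("peak table contains negative raw intensities")
        self.data = data.astype(float)
        self.normalized = normalized

    # -- basic accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, sample_ids) -> "PeakTable":
        return PeakTable(self.data.loc[list(sample_ids)], normalized=self.normalized)

    def copy(self) -> "PeakTable":
        return PeakTable(self.data.copy(), normalized=self.normalized)

    def __repr__(self) -> str:
        n, m = self.shape
        state = "normalized" if self.normalized else "raw"
        return f"PeakTable({n} samples × {m} metabolites, {state})"


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_SAMPLE_COLS = ["sample_id", "patient_id", "tissue_type", "tissue_weight", "tnm_stage"]
_MET_COLS = [
    "metabolite_id",
    "display_name",
    "chemical_class",
    "internal_standard_id",
    "ionization_mode",
]


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_peak_table(
    path,
    metadata_path,
    metabolite_metadata_path=None,
) -> tuple[PeakTable, list[SampleRecord], list[MetaboliteRecord]]:
    """Read a peak table plus metadata from delimited text.

    The table has one row per sample with the sample id in the first column.
    Every sample in the table must appear in the metadata; samples present in
    the metadata but absent from the table are rejected as well, so the two
    files always describe the same cohort.
    """
    raw = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    raw.index = raw.index.astype(str)
    raw.index.name = None
    raw.columns.name = None
    for col in raw.columns:
        bad = raw[col].apply(lambda v: not _is_number(v))
        if bad.any():
            row = raw.index[int(bad.to_numpy().argmax())]
            raise ValueError(
                f"non-numeric intensity at sample {row!r}, metabolite {col!r}: "
                f"{raw.loc[row, col]!r}"
            )
    table = PeakTable(raw.astype(float))

    samples = read_sample_metadata(metadata_path)
    meta_ids = [s.sample_id for s in samples]
    if len(set(meta_ids)) != len(meta_ids):
        raise ValueError("duplicate sample ids in metadata")
    missing = set(table.sample_ids) - set(meta_ids)
    if missing:
        raise ValueError(f"samples in peak table missing from metadata: {sorted(missing)}")
    extra = set(meta_ids) - set(table.sample_ids)
    if extra:
        raise ValueError(f"metadata samples absent from peak table: {sorted(extra)}")
    order = {sid: i for i, sid in enumerate(table.sample_ids)}
    samples.sort(key=lambda s: order[s.sample_id])

    if metabolite_metadata_path is not None:
        mets = read_metabolite_metadata(metabolite_metadata_path)
        met_ids = [m.metabolite_id for m in mets]
        if set(met_ids) != set(table.metabolite_ids):
            diff = set(met_ids) ^ set(table.metabolite_ids)
            raise ValueError(f"metabolite annotation mismatch: {sorted(diff)}")
        morder = {mid: i for i, mid in enumerate(table.metabolite_ids)}
        mets.sort(key=lambda m: morder[m.metabolite_id])
    else:
        mets = [MetaboliteRecord(mid) for mid in table.metabolite_ids]
    return table, samples, mets


def _is_number(v) -> bool:
    if isinstance(v, (int, float, np.integer, np.floating)):
        return True
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def read_sample_metadata(path) -> list[SampleRecord]:
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    records = []
    extra_cols = [c for c in df.columns if c not in _SAMPLE_COLS]
    for _, row in df.iterrows():
        weight = row.get("tissue_weight", "")
        clinical = {c: row[c] for c in extra_cols if row[c] != ""}
        records.append(
            SampleRecord(
                sample_id=row["sample_id"],
                patient_id=row["patient_id"],
                tissue_type=row["tissue_type"],
                tissue_weight=float(weight) if weight not in ("", "NA") else None,
                tnm_stage=row.get("tnm_stage", "none") or "none",
                clinical_indices=clinical,
            )
        )
    return records


def read_metabolite_metadata(path) -> list[MetaboliteRecord]:
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    records = []
    for _, row in df.iterrows():
        isd = row.get("internal_standard_id", "")
        records.append(
            MetaboliteRecord(
                metabolite_id=row["metabolite_id"],
                display_name=row.get("display_name", "") or row["metabolite_id"],
                chemical_class=row.get("chemical_class", "other") or "other",
                internal_standard_id=isd if isd not in ("", "NA") else None,
                ionization_mode=row.get("ionization_mode", "ESI+") or "ESI+",
            )
        )
    return records


def write_peak_table(pt: PeakTable, path) -> None:
    pt.data.to_csv(path, sep=_sep_for(path), index_label="sample_id")


def write_sample_metadata(samples: list[SampleRecord], path) -> None:
    clinical_keys = sorted({k for s in samples for k in s.clinical_indices})
    rows = []
    for s in samples:
        row = {
            "sample_id": s.sample_id,
            "patient_id": s.patient_id,
            "tissue_type": s.tissue_type,
            "tissue_weight": "" if s.tissue_weight is None else s.tissue_weight,
            "tnm_stage": s.tnm_stage,
        }
        for k in clinical_keys:
            row[k] = s.clinical_indices.get(k, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=_sep_for(path), index=False)


def write_metabolite_metadata(mets: list[MetaboliteRecord], path) -> None:
    rows = [
        {
            "metabolite_id": m.metabolite_id,
            "display_name": m.display_name,
            "chemical_class": m.chemical_class,
            "internal_standard_id": m.internal_standard_id or "",
            "ionization_mode": m.ionization_mode,
        }
        for m in mets
    ]
    pd.DataFrame(rows).to_csv(path, sep=_sep_for(path), index=False)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def normalize_intensities(
    pt: PeakTable,
    samples: list[SampleRecord],
    mets: list[MetaboliteRecord],
    drop_internal_standards: bool = True,
) -> PeakTable:
    """Normalize raw responses by internal standard and tissue weight.

    normalized = raw / IS_response(same sample) / tissue_weight.  QC samples
    carry no tissue weight and are divided by the internal standard only.
    A zero or missing internal-standard response flags the cell missing (NaN)
    with a warning rather than aborting the run; a zero tissue weight is a
    hard error because it silently corrupts every metabolite of the sample.

    Spiked internal-standard columns (metabolites assigned to themselves)
    are dropped from the normalized table by default — they are reagents,
    not analytes.
    """
    if pt.normalized:
        raise ValueError("peak table is already normalized")
    by_id = {s.sample_id: s for s in samples}
    missing_meta = set(pt.sample_ids) - set(by_id)
    if missing_meta:
        raise ValueError(f"samples without metadata: {sorted(missing_meta)}")

    out = pt.data.copy()
    is_map = {m.metabolite_id: m.internal_standard_id for m in mets}
    unassigned = [mid for mid in pt.metabolite_ids if is_map.get(mid) is None]
    if unassigned:
        raise ValueError(f"metabolites without internal-standard assignment: {unassigned}")
    absent_is = sorted({isd for isd in is_map.values() if isd not in pt.data.columns})
    if absent_is:
        raise ValueError(f"internal standards not measured: {absent_is}")

    for mid in pt.metabolite_ids:
        is_col = pt.data[is_map[mid]].to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = pt.data[mid].to_numpy() / is_col
        zero = ~(is_col > 0) | ~np.isfinite(is_col)
        if zero.any():
            bad = [pt.sample_ids[i] for i in np.flatnonzero(zero)]
            warnings.warn(
                f"internal standard {is_map[mid]!r} is zero/missing in samples "
                f"{bad}; flagging {mid!r} missing there"
            )
            vals[zero] = np.nan
        out[mid] = vals

    weights = np.ones(len(pt.sample_ids))
    for i, sid in enumerate(pt.sample_ids):
        rec = by_id[sid]
        if rec.is_qc:
            continue
        if rec.tissue_weight is None or rec.tissue_weight == 0:
            raise ValueError(f"tissue sample {sid!r} has zero/missing tissue weight")
        weights[i] = rec.tissue_weight
    out = out.div(weights, axis=0)
    if drop_internal_standards:
        self_assigned = [mid for mid in pt.metabolite_ids if is_map[mid] == mid]
        out = out.drop(columns=self_assigned)
    return PeakTable(out, normalized=True)


# ---------------------------------------------------------------------------
# QC RSD
# ---------------------------------------------------------------------------


def compute_qc_rsd(
    pt: PeakTable,
    samples: list[SampleRecord],
    ddof: int = 1,
) -> tuple[pd.Series, dict]:
    """Per-metabolite relative standard deviation over pooled-QC injections.

    RSD% = 100 * sd / mean across the QC samples.  The summary reports the
    fraction of metabolites with RSD below 20% and 30%, the conventional
    platform-stability cutoffs.  Metabolites with a zero QC mean get NaN.
    """
    qc_ids = [s.sample_id for s in samples if s.is_qc and s.sample_id in pt.data.index]
    if len(qc_ids) < 3:
        raise ValueError(f"need >= 3 QC samples to estimate RSD, found {len(qc_ids)}")
    qc = pt.data.loc[qc_ids]
    mean = qc.mean(axis=0)
    sd = qc.std(axis=0, ddof=ddof)
    with np.errstate(divide="ignore", invalid="ignore"):
        rsd = 100.0 * sd / mean
    rsd[mean == 0] = np.nan
    defined = rsd.dropna()
    summary = {
        "n_qc": len(qc_ids),
        "n_metabolites": pt.shape[1],
        "n_undefined": int(rsd.isna().sum()),
        "frac_rsd_lt_20": float((defined < 20).mean()) if len(defined) else float("nan"),
        "frac_rsd_lt_30": float((defined < 30).mean()) if len(defined) else float("nan"),
    }
    return rsd, summary


# ---------------------------------------------------------------------------
# Missing values
# ---------------------------------------------------------------------------


def handle_missing(pt: PeakTable, max_missing_fraction: float = 0.5) -> PeakTable:
    """Drop metabolites too often missing; impute the rest with half-minimum.

    Metabolites missing in more than ``max_missing_fraction`` of samples are
    removed (logged); any remaining missing cell is imputed with half the
    metabolite's observed minimum — the common below-detection-limit stand-in
    in peak-table metabolomics.
    """
    if not 0 <= max_missing_fraction <= 1:
        raise ValueError(f"max_missing_fraction must be in [0,1], got {max_missing_fraction}")
    frac_missing = pt.data.isna().mean(axis=0)
    dropped = frac_missing[frac_missing > max_missing_fraction].index.tolist()
    if dropped:
        logger.info("dropping %d metabolites with >%.0f%% missing: %s",
                    len(dropped), 100 * max_missing_fraction, dropped)
    kept = pt.data.drop(columns=dropped)
    if kept.isna().any().any():
        fill = kept.min(axis=0) / 2.0
        kept = kept.fillna(fill)
    return PeakTable(kept, normalized=pt.normalized)


# ---------------------------------------------------------------------------
# Pairing helpers used across modules
# ---------------------------------------------------------------------------


def paired_patient_samples(samples: list[SampleRecord]) -> list[tuple[str, str, str]]:
    """Return (patient_id, tumor_sample_id, adjacent_sample_id) per pair."""
    tumors: dict[str, str] = {}
    adjacents: dict[str, str] = {}
    for s in samples:
        if s.tissue_type == "tumor":
            if s.patient_id in tumors:
                raise ValueError(f"patient {s.patient_id!r} has two tumor samples")
            tumors[s.patient_id] = s.sample_id
        elif s.tissue_type == "adjacent":
            if s.patient_id in adjacents:
                raise ValueError(f"patient {s.patient_id!r} has two adjacent samples")
            adjacents[s.patient_id] = s.sample_id
    pairs = []
    for pid, t_sid in tumors.items():
        if pid in adjacents:
            pairs.append((pid, t_sid, adjacents[pid]))
    return pairs
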