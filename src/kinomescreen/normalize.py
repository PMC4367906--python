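"""Two-channel screen pre-processing.

The fixed pipeline order, matching the standard two-channel workflow for
cell-based assays, is:

1. non-specific filters (low-DAPI-intensity percentile filter, then removal
   of records whose mitotic count exceeds the total count),
2. per-plate normalization of each channel (divide by the plate median,
   rescale by the overall median),
3. per-record mitotic index MI = pH3 / DAPI (pseudocount on a zero
   numerator so log2 stays defined),
4. per-gene summarization (median over the gene's duplexes x images),
5. log2 transform and robust z-scores (median/MAD) across the screen.

All steps are exposed individually; :func:`preprocess_screen` runs them in
order and returns a :class:`NormalizedScreen`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as kio
from .exceptions import DegenerateScreenError, ValidationError

DEFAULT_MAD_CONSTANT = 1.4826  # normal-consistency factor


# ---------------------------------------------------------------------------
# Filters


def filter_low_dapi(
    records: pd.DataFrame, percentile: float = 0.01
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Remove records whose DAPI intensity falls in the lower tail.

    The cutoff is the empirical ``percentile`` quantile (linear
    interpolation) of all ``dapi_intensity`` values; records with intensity
    <= cutoff are removed. When the intensities have zero MAD (all tied)
    nothing is removed — a percentile filter on a constant column is
    meaningless.

    Returns ``(kept, removed, cutoff)``.
    """
    if len(records) == 0:
        raise ValidationError("filter_low_dapi: empty input")
    if len(records) < 2:
        raise ValidationError("filter_low_dapi: need at least 2 records")
    if not 0 < percentile < 1:
        raise ValidationError("percentile must be in (0, 1)")
    x = records["dapi_intensity"].to_numpy(dtype=float)
    med = np.median(x)
    if np.median(np.abs(x - med)) == 0:
        cutoff = float(np.min(x)) - 1.0  # removes nothing
        removed_mask = np.zeros(len(x), dtype=bool)
    else:
        cutoff = float(np.quantile(x, percentile))
        removed_mask = x <= cutoff
    kept = records.loc[~removed_mask].reset_index(drop=True)
    removed = records.loc[removed_mask].reset_index(drop=True)
    return kept, removed, cutoff


def filter_inconsistent(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove records where the mitotic count exceeds the total cell count.

    Strict inequality: ``ph3_count > dapi_count`` is removed, equality kept.
    """
    bad = (records["ph3_count"] > records["dapi_count"]).to_numpy()
    return (
        records.loc[~bad].reset_index(drop=True),
        records.loc[bad].reset_index(drop=True),
    )


# ---------------------------------------------------------------------------
# Plate normalization


def normalize_channel(values, plate_ids, sample_mask=None) -> np.ndarray:
    """Plate-median normalization of one channel.

    ``out[i] = values[i] / median(plate of i) * overall_median`` where plate
    medians and the overall median are computed on ``sample_mask`` records
    (all records if ``None``). After normalization every plate's median
    equals the overall pre-normalization median. Plates whose median is zero
    or undefined are excluded (their outputs are NaN) with a warning.
    """
    vals = np.asarray(values, dtype=float)
    plates = np.asarray(plate_ids)
    if vals.shape != plates.shape:
        raise ValidationError("values and plate_ids must align")
    mask = np.ones(len(vals), bool) if sample_mask is None else np.asarray(sample_mask, bool)
    if not mask.any():
        raise ValidationError("no reference records for plate medians")
    overall = float(np.median(vals[mask]))
    out = np.full(len(vals), np.nan)
    for plate in pd.unique(plates):
        on_plate = plates == plate
        ref = on_plate & mask
        med = float(np.median(vals[ref])) if ref.any() else np.nan
        if not np.isfinite(med) or med == 0:
            warnings.warn(
                f"plate {str(plate)!r} has zero/undefined channel median; excluded",
                stacklevel=2,
            )
            continue
        out[on_plate] = vals[on_plate] / med * overall
    return out


# ---------------------------------------------------------------------------
# Mitotic index


def compute_mi(dapi_count, ph3_count, pseudocount: float = 0.5):
    """Mitotic index MI = pH3 / DAPI, with a pseudocount on zero numerators.

    A zero pH3 count is replaced by ``pseudocount`` so the MI is strictly
    positive and log2-transformable. Records with DAPI count 0 (or NaN) get
    NaN — callers flag them as undefined rather than erroring, since a
    handful of empty images should not abort a screen.
    """
    dapi = np.asarray(dapi_count, dtype=float)
    ph3 = np.asarray(ph3_count, dtype=float)
    numer = np.where(ph3 == 0, pseudocount, ph3)
    with np.errstate(divide="ignore", invalid="ignore"):
        mi = np.where((dapi > 0) & np.isfinite(dapi), numer / dapi, np.nan)
    if np.ndim(dapi_count) == 0 and np.ndim(ph3_count) == 0:
        return float(mi)
    return mi


def summarize_gene(mi_values, statistic: str = "median") -> tuple[float, int]:
    """Summarize a gene's surviving per-image MI values.

    Returns ``(gene_mi, n_images_used)``; NaN inputs are ignored. With no
    surviving values the gene MI is NaN (reported NA, excluded downstream).
    """
    x = np.asarray(mi_values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) == 0:
        return float("nan"), 0
    if statistic == "median":
        return float(np.median(x)), len(x)
    if statistic == "mean":
        return float(np.mean(x)), len(x)
    raise ValidationError(f"unknown summary statistic {statistic!r}")


# ---------------------------------------------------------------------------
# Robust z-scores


def robust_zscore(values, scale_constant: float = DEFAULT_MAD_CONSTANT) -> np.ndarray:
    """z[i] = (x[i] - median) / MAD with MAD = scale_constant * median|x - median|.

    NaNs propagate; at least 3 finite values are required. A zero MAD raises
    :class:`DegenerateScreenError` — a screen where more than half the genes
    share one value needs inspection, not a z-score.
    """
    x = np.asarray(values, dtype=float)
    finite = x[np.isfinite(x)]
    if len(finite) < 3:
        raise ValidationError("robust_zscore: need >= 3 finite values")
    med = float(np.median(finite))
    mad = scale_constant * float(np.median(np.abs(finite - med)))
    if mad == 0:
        raise DegenerateScreenError(
            "MAD of the screen is 0; inspect the input distribution"
        )
    return (x - med) / mad


# ---------------------------------------------------------------------------
# Full pre-processing


@dataclass
class FilterReport:
    n_input: int = 0
    n_low_dapi_removed: int = 0
    n_inconsistent_removed: int = 0
    n_undefined_mi: int = 0
    low_dapi_cutoff: float = float("nan")


@dataclass
class NormalizedScreen:
    """Result of :func:`preprocess_screen`.

    genes : one row per gene — gene_symbol, mi, log2_mi, zscore,
        n_images_used, flags (semicolon-joined filter flags).
    records : the surviving per-image records with normalized counts and
        per-record MI.
    report : filter bookkeeping (kept + removed = input at every step).
    params : the parameter values the run used.
    """

    genes: pd.DataFrame
    records: pd.DataFrame
    report: FilterReport
    params: dict = field(default_factory=dict)


def preprocess_screen(
    measurements: pd.DataFrame,
    layout: pd.DataFrame | None = None,
    *,
    percentile: float = 0.01,
    pseudocount: float = 0.5,
    mad_constant: float = DEFAULT_MAD_CONSTANT,
    summary: str = "median",
    zscore_scope: str = "screen",
) -> NormalizedScreen:
    """Run the full pre-processing pipeline on joined measurement records.

    ``measurements`` must carry the layout columns (``gene_symbol``, ``role``)
    or a ``layout`` to join against. Plate medians are computed on sample
    wells so a strong positive control cannot bias them; normalized values
    are produced for control wells too (they feed plate QC). z-scores are
    computed across the screen by default, or within each gene's home plate
    with ``zscore_scope="plate"``.
    """
    records = measurements
    if "role" not in records.columns:
        if layout is None:
            raise ValidationError("measurements lack layout columns and no layout given")
        records = records.merge(
            layout[["plate_id", "well_id", "gene_symbol", "duplex_id", "role"]],
            on=["plate_id", "well_id"],
            how="inner",
        )
    if zscore_scope not in ("screen", "plate"):
        raise ValidationError("zscore_scope must be 'screen' or 'plate'")
    report = FilterReport(n_input=len(records))

    kept, removed_dapi, cutoff = filter_low_dapi(records, percentile)
    report.n_low_dapi_removed = len(removed_dapi)
    report.low_dapi_cutoff = cutoff
    kept, removed_inc = filter_inconsistent(kept)
    report.n_inconsistent_removed = len(removed_inc)

    sample_mask = (kept["role"] == kio.SAMPLE).to_numpy()
    kept = kept.copy()
    kept["dapi_norm"] = normalize_channel(
        kept["dapi_count"], kept["plate_id"], sample_mask
    )
    kept["ph3_norm"] = normalize_channel(
        kept["ph3_count"], kept["plate_id"], sample_mask
    )
    kept["mi"] = compute_mi(kept["dapi_norm"], kept["ph3_norm"], pseudocount)
    report.n_undefined_mi = int((~np.isfinite(kept["mi"])).sum())

    sample = kept.loc[sample_mask & (kept["gene_symbol"] != "")]
    gene_rows = []
    filtered_genes_dapi = set(removed_dapi.get("gene_symbol", pd.Series(dtype=str)))
    filtered_genes_inc = set(removed_inc.get("gene_symbol", pd.Series(dtype=str)))
    for gene, grp in sample.groupby("gene_symbol", sort=True):
        mi, n_used = summarize_gene(grp["mi"], summary)
        flags = []
        if gene in filtered_genes_dapi:
            flags.append("low_dapi_filtered")
        if gene in filtered_genes_inc:
            flags.append("inconsistent_filtered")
        gene_rows.append(
            {
                "gene_symbol": gene,
                "mi": mi,
                "log2_mi": np.log2(mi) if np.isfinite(mi) and mi > 0 else np.nan,
                "n_images_used": n_used,
                "flags": ";".join(flags),
                "plate_id": grp["plate_id"].iloc[0],
            }
        )
    genes = pd.DataFrame(
        gene_rows,
        columns=["gene_symbol", "mi", "log2_mi", "n_images_used", "flags", "plate_id"],
    )
    if zscore_scope == "screen":
        genes["zscore"] = robust_zscore(genes["log2_mi"], mad_constant)
    else:
        z = np.full(len(genes), np.nan)
        for _, idx in genes.groupby("plate_id").groups.items():
            z[genes.index.get_indexer(idx)] = robust_zscore(
                genes.loc[idx, "log2_mi"], mad_constant
            )
        genes["zscore"] = z
    genes = genes[
        ["gene_symbol", "mi", "log2_mi", "zscore", "n_images_used", "flags", "plate_id"]
    ]
    params = dict(
        percentile=percentile,
        pseudocount=pseudocount,
        mad_constant=mad_constant,
        summary=summary,
        zscore_scope=zscore_scope,
    )
    return NormalizedScreen(genes=genes, records=kept, report=report, params=params)
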