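"""Hit selection by the log2 median +/- k*MAD rule, low/high-MI grouping,
and plate-level control QC."""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import io as kio
from .exceptions import DegenerateScreenError, QCError, ValidationError
from .normalize import DEFAULT_MAD_CONSTANT, compute_mi

HIT = "hit"
NON_HIT = "non_hit"
LOW = "low"
HIGH = "high"
NONE = "none"


def call_hits(
    log2_mi: pd.Series,
    k: float = 2.0,
    mad_constant: float = DEFAULT_MAD_CONSTANT,
) -> pd.DataFrame:
    """Select hits whose log2 MI deviates from the screen median by more
    than ``k`` MADs.

    ``log2_mi`` is indexed by gene symbol (per-gene summarized values). A
    gene is a hit iff ``|x - median| > k * MAD`` with
    ``MAD = mad_constant * median(|x - median|)`` over the finite values;
    equality at the boundary is a non-hit ("above or below" reads strict).
    Hits with ``x < median`` form the low-MI group, ``x > median`` the
    high-MI group.

    Returns a DataFrame with columns gene_symbol, log2_mi, zscore,
    distance_in_mads, call, group. Genes with non-finite log2 MI are
    reported with call ``non_hit`` and group ``none`` (NA distance).
    """
    x = pd.Series(log2_mi).astype(float)
    finite = x[np.isfinite(x)]
    if len(finite) < 10:
        raise ValidationError("call_hits: need >= 10 genes with finite log2 MI")
    med = float(np.median(finite))
    mad = mad_constant * float(np.median(np.abs(finite - med)))
    if mad == 0:
        raise DegenerateScreenError("MAD is 0; hit thresholds are undefined")
    dist = (x - med) / mad
    is_hit = np.abs(x - med) > k * mad  # strict; NaN compares False
    group = np.where(~is_hit, NONE, np.where(x < med, LOW, HIGH))
    out = pd.DataFrame(
        {
            "gene_symbol": x.index.astype(str),
            "log2_mi": x.to_numpy(),
            "zscore": dist.to_numpy(),
            "distance_in_mads": dist.to_numpy(),
            "call": np.where(is_hit, HIT, NON_HIT),
            "group": group,
        }
    ).reset_index(drop=True)
    return out


def call_hits_per_duplex(
    log2_mi: pd.DataFrame,
    k: float = 2.0,
    mad_constant: float = DEFAULT_MAD_CONSTANT,
    min_duplex_hits: int = 2,
) -> pd.DataFrame:
    """Alternative hit calling on per-duplex values.

    ``log2_mi`` needs columns gene_symbol, duplex_id, log2_mi. Thresholds
    are computed on the pooled duplex distribution; a gene is a hit if at
    least ``min_duplex_hits`` of its duplexes pass on the same side. Genes
    whose passing duplexes disagree in direction are non-hits.
    """
    for col in ("gene_symbol", "duplex_id", "log2_mi"):
        if col not in log2_mi.columns:
            raise ValidationError(f"per-duplex table lacks column '{col}'")
    x = log2_mi["log2_mi"].astype(float)
    finite = x[np.isfinite(x)]
    if len(finite) < 10:
        raise ValidationError("call_hits_per_duplex: need >= 10 finite values")
    med = float(np.median(finite))
    mad = mad_constant * float(np.median(np.abs(finite - med)))
    if mad == 0:
        raise DegenerateScreenError("MAD is 0; hit thresholds are undefined")
    tab = log2_mi.assign(
        _low=(x < med - k * mad), _high=(x > med + k * mad)
    )
    rows = []
    for gene, grp in tab.groupby("gene_symbol", sort=True):
        n_low, n_high = int(grp["_low"].sum()), int(grp["_high"].sum())
        if n_low >= min_duplex_hits and n_high < min_duplex_hits:
            call, group = HIT, LOW
        elif n_high >= min_duplex_hits and n_low < min_duplex_hits:
            call, group = HIT, HIGH
        else:
            call, group = NON_HIT, NONE
        gmi = float(np.median(grp["log2_mi"].dropna())) if grp["log2_mi"].notna().any() else np.nan
        rows.append(
            {
                "gene_symbol": gene,
                "log2_mi": gmi,
                "zscore": (gmi - med) / mad if np.isfinite(gmi) else np.nan,
                "distance_in_mads": (gmi - med) / mad if np.isfinite(gmi) else np.nan,
                "call": call,
                "group": group,
            }
        )
    return pd.DataFrame(rows)


def classify_groups(hit_table: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Partition the hit set into alphabetically sorted low/high-MI lists."""
    hits = hit_table.loc[hit_table["call"] == HIT]
    low = sorted(hits.loc[hits["group"] == LOW, "gene_symbol"])
    high = sorted(hits.loc[hits["group"] == HIGH, "gene_symbol"])
    return low, high


def qc_controls(
    records: pd.DataFrame,
    layout: pd.DataFrame | None = None,
    min_separation: float = 3.0,
    pseudocount: float = 0.5,
    mad_constant: float = DEFAULT_MAD_CONSTANT,
) -> pd.DataFrame:
    """Per-plate control QC.

    For each plate, per-well MI values (counts pooled over the well's
    images) are scored as robust z against the plate's sample-well log2 MI
    distribution. Reports the median z of positive-control wells, the
    median z of negative-control wells (untreated and lipofectant pooled),
    their separation and a pass flag (``|pos - neg| >= min_separation``).
    A plate lacking a positive or a negative control raises :class:`QCError`
    naming the plate; failing plates are flagged, never dropped.
    """
    recs = records
    if "role" not in recs.columns:
        if layout is None:
            raise ValidationError("records lack a 'role' column and no layout given")
        recs = recs.merge(
            layout[["plate_id", "well_id", "role"]], on=["plate_id", "well_id"], how="inner"
        )
    wells = (
        recs.groupby(["plate_id", "well_id", "role"], sort=True)[["dapi_count", "ph3_count"]]
        .sum()
        .reset_index()
    )
    wells["log2_mi"] = np.log2(
        compute_mi(wells["dapi_count"], wells["ph3_count"], pseudocount)
    )
    rows = []
    for plate, grp in wells.groupby("plate_id", sort=True):
        pos = grp.loc[grp["role"] == kio.POSITIVE_CONTROL, "log2_mi"]
        neg = grp.loc[grp["role"].isin(kio.NEGATIVE_CONTROL_ROLES), "log2_mi"]
        if len(pos) == 0:
            raise QCError(f"plate {plate!r} has no positive-control well")
        if len(neg) == 0:
            raise QCError(f"plate {plate!r} has no negative-control well")
        samples = grp.loc[grp["role"] == kio.SAMPLE, "log2_mi"].to_numpy()
        samples = samples[np.isfinite(samples)]
        if len(samples) < 3:
            raise QCError(f"plate {plate!r} has too few sample wells for QC")
        med = float(np.median(samples))
        mad = mad_constant * float(np.median(np.abs(samples - med)))
        if mad == 0:
            raise DegenerateScreenError(f"plate {plate!r}: sample MAD is 0")
        pos_z = float(np.median((pos - med) / mad))
        neg_z = float(np.median((neg - med) / mad))
        rows.append(
            {
                "plate_id": plate,
                "positive_control_z": pos_z,
                "negative_control_z": neg_z,
                "separation": abs(pos_z - neg_z),
                "passed": abs(pos_z - neg_z) >= min_separation,
            }
        )
    return pd.DataFrame(rows)
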