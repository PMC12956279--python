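"""Comparative-CT quantification of RT-DNA abundance and unit conversions.

The qPCR design uses two amplicons: an *inside* amplicon templated by both
the single-stranded RT-DNA and the expression plasmid, and an *outside*
amplicon templated by the plasmid alone.  The inside/outside ΔCT contrast,
compared between induced and uninduced cultures, gives the fold enrichment
F = 2^(−ΔΔCT) of (RT-DNA + plasmid) over plasmid.  Because the inside
amplicon counts N_rt + N_p templates and the outside counts N_p, the
per-cell RT-DNA copy number back-calculates as N_rt = (F − 1)·N_p, and a
cytoplasmic volume converts copies to molar concentration.

Also provided: densitometry normalization (intensity per nucleotide,
relative to a reference lane) and OD-normalized plate-reader fluorescence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

AVOGADRO = 6.02214076e23  # 1/mol

__all__ = [
    "AVOGADRO",
    "CtMeasurement",
    "FoldEnrichment",
    "CopyEstimate",
    "GelLane",
    "PlateReading",
    "delta_ct",
    "fold_enrichment",
    "copies_per_cell",
    "molar_concentration",
    "copy_estimate",
    "fold_enrichment_from_table",
    "length_corrected_fold",
    "od_normalized_fluorescence",
]


@dataclass(frozen=True)
class CtMeasurement:
    sample: str
    condition: str  # "induced" | "uninduced"
    primer_set: str  # "inside" | "outside"
    ct: float
    replicate: int = 0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.ct) and self.ct > 0):
            raise ValueError(f"ct must be finite and positive, got {self.ct}")
        if self.condition not in ("induced", "uninduced"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.primer_set not in ("inside", "outside"):
            raise ValueError(f"unknown primer_set {self.primer_set!r}")


@dataclass(frozen=True)
class FoldEnrichment:
    dct_induced: float
    dct_uninduced: float
    ddct: float
    fold: float


@dataclass(frozen=True)
class CopyEstimate:
    fold: float
    plasmid_copies_low: float
    plasmid_copies_high: float
    rtdna_low: float
    rtdna_high: float
    volume: float  # liters
    conc_low: float  # mol/L
    conc_high: float
    below_background: bool = False


@dataclass(frozen=True)
class GelLane:
    label: str
    intensity: float
    length: int

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValueError("intensity must be >= 0")
        if self.length < 1:
            raise ValueError("length must be >= 1 nt")


@dataclass(frozen=True)
class PlateReading:
    fluorescence: float
    od600: float
    dilution: float = 1.0

    def __post_init__(self) -> None:
        if self.od600 <= 0:
            raise ValueError("od600 must be > 0")
        if self.dilution < 1:
            raise ValueError("dilution factor must be >= 1")


def delta_ct(inside: float | Sequence[float], outside: float | Sequence[float]) -> float:
    """ΔCT = mean(inside CTs) − mean(outside CTs).

    Replicate CT values are averaged arithmetically before differencing.
    """
    ins = np.atleast_1d(np.asarray(inside, dtype=float))
    out = np.atleast_1d(np.asarray(outside, dtype=float))
    if not (np.all(np.isfinite(ins)) and np.all(np.isfinite(out))):
        raise ValueError("CT values must be finite")
    return float(ins.mean() - out.mean())


def fold_enrichment(
    dct_induced: float, dct_uninduced: float, efficiency: float = 2.0
) -> FoldEnrichment:
    """Fold enrichment = efficiency^(−ΔΔCT) with ΔΔCT = ΔCT_induced − ΔCT_uninduced.

    The default per-cycle amplification efficiency of 2.0 gives the standard
    2^(−ΔΔCT) comparative-CT estimator.
    """
    if not (math.isfinite(dct_induced) and math.isfinite(dct_uninduced)):
        raise ValueError("ΔCT values must be finite")
    ddct = dct_induced - dct_uninduced
    return FoldEnrichment(
        dct_induced=dct_induced,
        dct_uninduced=dct_uninduced,
        ddct=ddct,
        fold=efficiency ** (-ddct),
    )


def copies_per_cell(fold: float, plasmid_copies: float) -> float:
    """RT-DNA molecules per cell: (fold − 1) × plasmid copy number.

    The inside amplicon templates on RT-DNA + plasmid while the outside
    amplicon templates on plasmid only, so an enrichment F implies
    N_rt = (F − 1)·N_p.  A fold below 1 (legitimate in uninduced samples)
    is clamped to zero copies.
    """
    if plasmid_copies <= 0:
        raise ValueError("plasmid_copies must be > 0")
    if fold < 1:
        return 0.0
    return (fold - 1.0) * plasmid_copies


def molar_concentration(molecules: float, volume: float) -> float:
    """Convert a per-cell molecule count to mol/L for a given cell volume."""
    if volume <= 0:
        raise ValueError("volume must be > 0 L")
    if molecules < 0:
        raise ValueError("molecules must be >= 0")
    return molecules / (AVOGADRO * volume)


def copy_estimate(
    fold: float,
    plasmid_copies_low: float = 15.0,
    plasmid_copies_high: float = 20.0,
    volume: float = 7e-16,
) -> CopyEstimate:
    """Bundle the copy-number and concentration back-calculation with bounds.

    Defaults follow a pBR322-origin expression plasmid (15–20 copies per
    cell) and an average E. coli cytoplasmic volume of 7e-16 L.
    """
    below = fold < 1
    low = copies_per_cell(fold, plasmid_copies_low)
    high = copies_per_cell(fold, plasmid_copies_high)
    return CopyEstimate(
        fold=fold,
        plasmid_copies_low=plasmid_copies_low,
        plasmid_copies_high=plasmid_copies_high,
        rtdna_low=low,
        rtdna_high=high,
        volume=volume,
        conc_low=molar_concentration(low, volume),
        conc_high=molar_concentration(high, volume),
        below_background=below,
    )


def fold_enrichment_from_table(
    table: pd.DataFrame, efficiency: float = 2.0
) -> pd.DataFrame:
    """Comparative-CT analysis of a tidy CT table.

    Expects columns ``sample, condition, primer_set, replicate, ct``.
    Technical CT replicates are averaged per (sample, condition, primer_set);
    fold enrichment is computed per biological replicate (``sample``) and the
    result carries one row per sample plus mean ± SD summary attributes.
    """
    required = {"sample", "condition", "primer_set", "ct"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"CT table missing columns: {sorted(missing)}")
    means = (
        table.groupby(["sample", "condition", "primer_set"])["ct"].mean().unstack("primer_set")
    )
    if not {"inside", "outside"} <= set(means.columns):
        raise ValueError("CT table must contain both 'inside' and 'outside' primer sets")
    dct = (means["inside"] - means["outside"]).unstack("condition")
    if not {"induced", "uninduced"} <= set(dct.columns):
        raise ValueError("CT table must contain both 'induced' and 'uninduced' conditions")
    rows = []
    for sample, row in dct.iterrows():
        fe = fold_enrichment(row["induced"], row["uninduced"], efficiency=efficiency)
        rows.append(
            {
                "sample": sample,
                "dct_induced": fe.dct_induced,
                "dct_uninduced": fe.dct_uninduced,
                "ddct": fe.ddct,
                "fold": fe.fold,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["fold_mean"] = float(out["fold"].mean())
    out.attrs["fold_sd"] = float(out["fold"].std(ddof=1)) if len(out) > 1 else 0.0
    return out


def length_corrected_fold(
    lanes: Iterable[GelLane], reference: str
) -> dict[str, float]:
    """Per-lane fold change of length-normalized band intensity vs a reference lane.

    fold(x) = (I_x / L_x) / (I_ref / L_ref); the reference maps to 1.0.
    """
    lanes = list(lanes)
    by_label = {lane.label: lane for lane in lanes}
    if reference not in by_label:
        raise ValueError(f"reference lane {reference!r} not present")
    ref = by_label[reference]
    if ref.intensity <= 0:
        raise ValueError("reference lane intensity must be > 0")
    ref_density = ref.intensity / ref.length
    return {lane.label: (lane.intensity / lane.length) / ref_density for lane in lanes}


def od_normalized_fluorescence(reading: PlateReading) -> float:
    """Fluorescence per undiluted-equivalent OD600.

    A culture diluted D-fold before the OD read has undiluted OD = od600·D,
    so the normalized signal is F / (od600 · D).
    """
    return reading.fluorescence / (reading.od600 * reading.dilution)
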