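"""Chemical-shift-perturbation and intensity-broadening titration analysis.

The combined amide shift change between a titration point and the
peptide-free reference is the weighted two-nucleus norm

    Δδ_obs = sqrt( (δ1H)^2 + ((1/6) δ15N)^2 )   [ppm]

with the nitrogen change down-weighted by exactly 1/6.  Binding strength
across protein variants is ranked qualitatively from how fast the
reporter-residue HSQC peaks broaden as ligand is added: for each reporter
the normalised intensity-vs-ratio decay curve is integrated and the score
is 1 - AUC/span (larger = faster broadening = stronger apparent binding).
Peaks broadened beyond detection count as intensity zero from the first
missing titration point onward.  The ranking is deliberately an ordering,
not a Kd fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PeakRecord",
    "TitrationPoint",
    "TitrationSeries",
    "CSPRecord",
    "csp",
    "compute_csp",
    "csp_profile",
    "intensity_profile",
    "rank_affinity",
    "read_peaklist",
    "write_peaklist",
]

#: The paper-standard reporter residues (carboxylate-binding loop L260/G261,
#: binding-groove periphery G279/G285) in hDVL3 numbering.
DEFAULT_REPORTERS = (260, 261, 279, 285)

N_WEIGHT = 1.0 / 6.0


@dataclass(frozen=True)
class PeakRecord:
    residue_number: int
    delta_1H_ppm: float
    delta_15N_ppm: float
    intensity: float

    def __post_init__(self):
        if self.intensity < 0:
            raise ValueError("negative peak intensity")


@dataclass
class TitrationPoint:
    ligand_ratio: float
    peaks: dict = field(default_factory=dict)  # residue_number -> PeakRecord


@dataclass
class TitrationSeries:
    variant_label: str
    points: list  # list[TitrationPoint], sorted by ligand_ratio

    def __post_init__(self):
        self.points = sorted(self.points, key=lambda p: p.ligand_ratio)
        ratios = [p.ligand_ratio for p in self.points]
        if len(ratios) == 0:
            raise ValueError("titration series has no points")
        if ratios[0] != 0.0:
            raise ValueError("first titration point must be the no-peptide reference (ratio 0)")
        if np.any(np.diff(ratios) <= 0):
            raise ValueError("ligand ratios must be strictly increasing")

    @property
    def ratios(self) -> np.ndarray:
        return np.array([p.ligand_ratio for p in self.points])

    @property
    def reference(self) -> TitrationPoint:
        return self.points[0]


@dataclass
class CSPRecord:
    residue_number: int
    ligand_ratios: np.ndarray
    delta_obs_ppm: np.ndarray


def csp(delta_h_ppm: float, delta_n_ppm: float) -> float:
    """Weighted combined shift change for given 1H and 15N changes."""
    return float(np.hypot(delta_h_ppm, N_WEIGHT * delta_n_ppm))


def compute_csp(point: PeakRecord, reference: PeakRecord) -> float:
    """Δδ_obs of a peak relative to its no-peptide reference position."""
    if point.residue_number != reference.residue_number:
        raise ValueError(
            f"residue mismatch: {point.residue_number} vs {reference.residue_number}"
        )
    return csp(point.delta_1H_ppm - reference.delta_1H_ppm,
               point.delta_15N_ppm - reference.delta_15N_ppm)


def csp_profile(series: TitrationSeries, residue: int) -> CSPRecord:
    """Δδ_obs of one residue across all titration points (0 at reference)."""
    ref = series.reference.peaks.get(residue)
    if ref is None:
        raise KeyError(f"residue {residue} absent from the reference point")
    ratios, values = [], []
    for p in series.points:
        pk = p.peaks.get(residue)
        if pk is None:
            continue  # broadened out: no position to measure
        ratios.append(p.ligand_ratio)
        values.append(compute_csp(pk, ref))
    return CSPRecord(residue, np.array(ratios), np.array(values))


def intensity_profile(series: TitrationSeries, residue: int) -> pd.DataFrame:
    """Reference-normalised peak intensity vs ligand ratio.

    Missing peaks (broadened beyond detection) are reported as intensity 0
    with ``beyond_detection=True`` — and remain 0 from the first missing
    point onward even if a later point lists the peak again.
    """
    ref = series.reference.peaks.get(residue)
    if ref is None:
        raise KeyError(f"residue {residue} absent from the reference point")
    if ref.intensity <= 0:
        raise ValueError(f"residue {residue} has non-positive reference intensity")
    rows = []
    vanished = False
    for p in series.points:
        pk = p.peaks.get(residue)
        if pk is None or vanished:
            vanished = True
            rows.append((p.ligand_ratio, 0.0, True))
        else:
            rows.append((p.ligand_ratio, pk.intensity / ref.intensity, False))
    return pd.DataFrame(rows, columns=["ligand_ratio", "intensity", "beyond_detection"])


def _broadening_score(series: TitrationSeries, reporters) -> float:
    scores = []
    for res in reporters:
        prof = intensity_profile(series, res)
        x = prof["ligand_ratio"].to_numpy()
        y = np.clip(prof["intensity"].to_numpy(), 0.0, None)
        span = x[-1] - x[0]
        if span <= 0:
            raise ValueError("titration needs more than one ratio to rank")
        scores.append(1.0 - np.trapezoid(y, x) / span)
    return float(np.mean(scores))


def rank_affinity(
    series_set: list[TitrationSeries],
    reporter_residues=DEFAULT_REPORTERS,
    *,
    tie_tolerance: float = 1e-9,
) -> list[dict]:
    """Order variants by apparent binding strength (descending score).

    The score is the mean, over reporter residues, of 1 - AUC of the
    normalised intensity-decay curve (normalised by the ratio span).  Ties
    within ``tie_tolerance`` are reported via a shared ``rank``, not broken.
    """
    for s in series_set:
        missing = [r for r in reporter_residues if r not in s.reference.peaks]
        if missing:
            raise KeyError(f"variant {s.variant_label}: reporters missing at reference: {missing}")
    scored = sorted(
        ({"variant": s.variant_label, "score": _broadening_score(s, reporter_residues)}
         for s in series_set),
        key=lambda d: -d["score"],
    )
    rank = 0
    for i, entry in enumerate(scored):
        if i > 0 and abs(entry["score"] - scored[i - 1]["score"]) > tie_tolerance:
            rank = i
        entry["rank"] = rank
    return scored


_COLUMNS = ["variant", "ligand_ratio", "residue", "d1H", "d15N", "intensity"]


def write_peaklist(path: str | Path, series: TitrationSeries) -> None:
    rows = []
    for p in series.points:
        for res in sorted(p.peaks):
            pk = p.peaks[res]
            rows.append((series.variant_label, p.ligand_ratio, res,
                         pk.delta_1H_ppm, pk.delta_15N_ppm, pk.intensity))
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False, float_format="%.6f")


def read_peaklist(path: str | Path) -> TitrationSeries:
    """Read a titration peak list CSV (columns: variant, ligand_ratio,
    residue, d1H, d15N, intensity).  Row order is irrelevant; duplicate
    (point, residue) pairs are an error."""
    df = pd.read_csv(path)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"peak list lacks columns {missing}")
    variants = df["variant"].unique()
    if len(variants) != 1:
        raise ValueError(f"peak list must hold exactly one variant, found {list(variants)}")
    if df.duplicated(subset=["ligand_ratio", "residue"]).any():
        dup = df[df.duplicated(subset=["ligand_ratio", "residue"])].iloc[0]
        raise ValueError(f"duplicate peak: residue {int(dup.residue)} at ratio {dup.ligand_ratio}")
    points = []
    for ratio, grp in df.groupby("ligand_ratio"):
        peaks = {
            int(row.residue): PeakRecord(int(row.residue), float(row.d1H),
                                         float(row.d15N), float(row.intensity))
            for row in grp.itertuples()
        }
        points.append(TitrationPoint(float(ratio), peaks))
    return TitrationSeries(str(variants[0]), points)
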