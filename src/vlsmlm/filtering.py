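"""Apply a vls calibration to localization tables and classify clusters.

The filter keeps a localization iff its fitted width is at most the
calibrated maximum AND its amplitude is at least the calibrated minimum.
For reporting, rejection is attributed in the calibration's two-step order:
a localization failing the width cut counts as width-rejected even if its
amplitude would also fail; the kept set itself is order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .calibration import VlsCalibration

__all__ = [
    "NOISE_CLUSTER_ID",
    "FilterReport",
    "ClusterSummary",
    "apply_thresholds",
    "group_clusters",
    "classify_clusters",
]

#: reserved cluster id for unassigned localizations
NOISE_CLUSTER_ID = -1


@dataclass(frozen=True)
class FilterReport:
    """Bookkeeping of one filtering pass."""

    n_input: int
    n_kept: int
    n_rejected_width: int
    n_rejected_amplitude: int
    n_rejected_invalid: int
    width_max_nm: float
    amplitude_min_photons_um2: float

    def __post_init__(self) -> None:
        total = (
            self.n_kept
            + self.n_rejected_width
            + self.n_rejected_amplitude
            + self.n_rejected_invalid
        )
        if total != self.n_input:
            raise ValueError("filter report counts do not add up")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_kept": self.n_kept,
            "n_rejected_width": self.n_rejected_width,
            "n_rejected_amplitude": self.n_rejected_amplitude,
            "n_rejected_invalid": self.n_rejected_invalid,
            "width_max_nm": self.width_max_nm,
            "amplitude_min_photons_um2": self.amplitude_min_photons_um2,
        }


@dataclass(frozen=True)
class ClusterSummary:
    """In/out-of-vls counts of one cluster of localizations."""

    cluster_id: int
    n_in_vls: int
    n_out: int

    @property
    def category(self) -> str:
        """fully-in, fully-out or partial cluster membership."""
        if self.n_in_vls > 0 and self.n_out == 0:
            return "fully-in"
        if self.n_in_vls == 0:
            return "fully-out"
        return "partial"


def _rejection_masks(
    table: pd.DataFrame, width_max: float, amplitude_min: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(kept, invalid, width-rejected, amplitude-rejected) boolean masks."""
    width = pd.to_numeric(table["sigma_nm"], errors="coerce").to_numpy(dtype=float)
    amp = pd.to_numeric(table["amplitude_photons_um2"], errors="coerce").to_numpy(dtype=float)
    invalid = np.isnan(width) | np.isnan(amp)
    if "fit_ok" in table.columns:
        invalid |= ~table["fit_ok"].astype(bool).to_numpy()
    with np.errstate(invalid="ignore"):
        width_fail = ~invalid & (width > width_max)
        amp_fail = ~invalid & ~width_fail & (amp < amplitude_min)
    kept = ~invalid & ~width_fail & ~amp_fail
    return kept, invalid, width_fail, amp_fail


def apply_thresholds(
    localizations: pd.DataFrame,
    calibration: VlsCalibration,
) -> tuple[pd.DataFrame, FilterReport]:
    """Keep localizations inside the calibrated virtual light-sheet.

    Rows with missing or non-finite width/amplitude, or flagged
    ``fit_ok=False``, are rejected up front and reported separately.  Row
    order is preserved.  Applying the same calibration twice is a no-op.
    """
    width_max = calibration.width_max_nm
    amplitude_min = calibration.amplitude_min_photons_um2
    if len(localizations) == 0:
        report = FilterReport(0, 0, 0, 0, 0, width_max, amplitude_min)
        return localizations.copy(), report
    kept, invalid, width_fail, amp_fail = _rejection_masks(
        localizations, width_max, amplitude_min
    )
    report = FilterReport(
        n_input=len(localizations),
        n_kept=int(kept.sum()),
        n_rejected_width=int(width_fail.sum()),
        n_rejected_amplitude=int(amp_fail.sum()),
        n_rejected_invalid=int(invalid.sum()),
        width_max_nm=width_max,
        amplitude_min_photons_um2=amplitude_min,
    )
    return localizations[kept], report


def group_clusters(
    localizations: pd.DataFrame,
    radius_nm: float,
    min_points: int,
) -> np.ndarray:
    """Density-connected grouping of localizations by lateral proximity.

    Links every pair of localizations within ``radius_nm`` of each other
    and labels each connected component with at least ``min_points``
    members as a cluster (ids 0, 1, ... in order of first appearance);
    everything else gets :data:`NOISE_CLUSTER_ID`.  This is a stand-in for
    whatever cluster definition a specific experiment uses — any external
    assignment can be passed to :func:`classify_clusters` instead.
    """
    if radius_nm <= 0:
        raise ValueError("radius_nm must be > 0")
    n = len(localizations)
    if n == 0:
        return np.empty(0, dtype=int)
    xy = localizations[["x_nm", "y_nm"]].to_numpy(dtype=float)
    tree = cKDTree(xy)
    pairs = tree.query_pairs(radius_nm, output_type="ndarray")
    rows = np.concatenate([pairs[:, 0], pairs[:, 1]]) if len(pairs) else np.empty(0, int)
    cols = np.concatenate([pairs[:, 1], pairs[:, 0]]) if len(pairs) else np.empty(0, int)
    graph = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    _, labels = connected_components(graph, directed=False)

    assignment = np.full(n, NOISE_CLUSTER_ID, dtype=int)
    next_id = 0
    seen: dict[int, int] = {}
    counts = np.bincount(labels)
    for i in range(n):
        comp = labels[i]
        if counts[comp] < min_points:
            continue
        if comp not in seen:
            seen[comp] = next_id
            next_id += 1
        assignment[i] = seen[comp]
    return assignment


def classify_clusters(
    localizations: pd.DataFrame,
    cluster_assignment: np.ndarray,
    calibration: VlsCalibration,
) -> list[ClusterSummary]:
    """Count kept (in-vls) vs rejected localizations per cluster.

    Clusters fully inside the virtual light-sheet keep all their
    localizations; clusters fully outside lose all of them; clusters
    straddling the slab edge are partial.  Unassigned localizations are
    collected under :data:`NOISE_CLUSTER_ID`.
    """
    cluster_assignment = np.asarray(cluster_assignment, dtype=int)
    if len(cluster_assignment) != len(localizations):
        raise ValueError("cluster_assignment length must match the table")
    kept, *_ = _rejection_masks(
        localizations, calibration.width_max_nm, calibration.amplitude_min_photons_um2
    )
    summaries = []
    for cid in sorted(np.unique(cluster_assignment)):
        member = cluster_assignment == cid
        n_in = int((member & kept).sum())
        summaries.append(
            ClusterSummary(cluster_id=int(cid), n_in_vls=n_in,
                           n_out=int(member.sum()) - n_in)
        )
    return summaries
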