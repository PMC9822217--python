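"""Grouping elements into material sets of similar modulus.

A mapped mesh can easily carry thousands of distinct element moduli; FE
solvers want a manageable number of material cards.  The range of observed
values (modulus by default, HU as the classical alternative) is divided
into ``n_bins`` equal-width intervals, half-open ``(lo, hi]`` with the
minimum value absorbed into the first bin, each non-empty interval becomes
a material set, and each set is summarised by a representative modulus
(volume-weighted mean by default, interval midpoint as an option) and by
the volume fraction of the mesh it occupies.  The (modulus, volume
fraction) pairs form the material-distribution curve of the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import BinningError
from .femesh import FEMesh
from .hu_mapping import MaterialAssignment

__all__ = [
    "MaterialBin",
    "bin_elements",
    "volume_fractions",
    "representative_modulus",
    "distribution_table",
    "bin_id_per_element",
]

DEFAULT_N_BINS = 50


@dataclass
class MaterialBin:
    """One material set: a value interval and its member elements."""

    index: int
    interval: tuple[float, float]  # (lo, hi], binning-space units
    element_ids: np.ndarray
    representative_modulus: float = float("nan")  # MPa
    volume_fraction: float = float("nan")
    member_modulus: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def n_elements(self) -> int:
        return len(self.element_ids)


def bin_elements(
    assignment: MaterialAssignment,
    n_bins: int = DEFAULT_N_BINS,
    space: str = "modulus",
) -> list[MaterialBin]:
    """Partition elements into equal-width bins of modulus (or HU).

    Intervals are half-open ``(lo, hi]`` between the observed minimum and
    maximum; the minimum itself belongs to the first bin and the maximum
    to the last.  Empty bins are dropped with their indices preserved.
    """
    if n_bins < 1:
        raise BinningError(f"n_bins must be >= 1, got {n_bins}")
    if len(assignment.elem_ids) == 0:
        raise BinningError("assignment is empty")
    if space == "modulus":
        values = np.asarray(assignment.young_modulus, dtype=np.float64)
    elif space == "hu":
        values = np.asarray(assignment.hu_mean, dtype=np.float64)
    else:
        raise BinningError(f"space must be 'modulus' or 'hu', got {space!r}")

    vmin, vmax = float(values.min()), float(values.max())
    if vmin == vmax:
        edges = np.array([vmin, vmax])
        idx = np.zeros(len(values), dtype=np.int64)
        n_bins_eff = 1
    else:
        edges = np.linspace(vmin, vmax, n_bins + 1)
        width = (vmax - vmin) / n_bins
        # (lo, hi] convention: value exactly on an internal edge goes left
        idx = np.ceil((values - vmin) / width).astype(np.int64) - 1
        idx = np.clip(idx, 0, n_bins - 1)  # the minimum joins bin 0
        n_bins_eff = n_bins

    bins: list[MaterialBin] = []
    moduli = np.asarray(assignment.young_modulus, dtype=np.float64)
    for k in range(n_bins_eff):
        mask = idx == k
        if not mask.any():
            continue
        bins.append(
            MaterialBin(
                index=k,
                interval=(float(edges[k]), float(edges[k + 1])),
                element_ids=assignment.elem_ids[mask].copy(),
                member_modulus=moduli[mask].copy(),
            )
        )
    return bins


def volume_fractions(bins: list[MaterialBin], mesh: FEMesh) -> list[MaterialBin]:
    """Fill each bin's volume fraction: sum of member volumes / mesh volume."""
    vols = mesh.volumes()
    row = {int(e): i for i, e in enumerate(mesh.elem_ids)}
    total = float(vols.sum())
    if total <= 0:
        raise BinningError("mesh has zero total volume")
    for b in bins:
        member_vols = vols[[row[int(e)] for e in b.element_ids]]
        b.volume_fraction = float(member_vols.sum()) / total
    return bins


def representative_modulus(
    b: MaterialBin, mode: str = "volume_weighted_mean", mesh: FEMesh | None = None
) -> float:
    """Representative E (MPa) for one bin.

    ``volume_weighted_mean`` (default) weights member moduli by element
    volume (equal weights if no mesh is supplied); ``midpoint`` is the
    interval center.
    """
    if b.n_elements == 0:
        raise BinningError(f"bin {b.index} is empty")
    if mode == "midpoint":
        return 0.5 * (b.interval[0] + b.interval[1])
    if mode != "volume_weighted_mean":
        raise BinningError(f"unknown representative mode {mode!r}")
    if mesh is None:
        return float(np.mean(b.member_modulus))
    vols = mesh.volumes()
    row = {int(e): i for i, e in enumerate(mesh.elem_ids)}
    w = vols[[row[int(e)] for e in b.element_ids]]
    return float(np.average(b.member_modulus, weights=w))


def summarize_bins(
    bins: list[MaterialBin],
    mesh: FEMesh,
    mode: str = "volume_weighted_mean",
) -> list[MaterialBin]:
    """Fill volume fractions and representative moduli in place."""
    volume_fractions(bins, mesh)
    for b in bins:
        b.representative_modulus = representative_modulus(b, mode=mode, mesh=mesh)
    return bins


def distribution_table(bins: list[MaterialBin]) -> pd.DataFrame:
    """(representative modulus, volume fraction) rows, sorted by modulus.

    Columns: ``bin``, ``E_repr_MPa``, ``volume_fraction``, ``n_elements``.
    """
    rows = [
        {
            "bin": b.index,
            "E_repr_MPa": b.representative_modulus,
            "volume_fraction": b.volume_fraction,
            "n_elements": b.n_elements,
        }
        for b in bins
        if b.n_elements > 0
    ]
    df = pd.DataFrame(rows)
    return df.sort_values("E_repr_MPa").reset_index(drop=True)


def bin_id_per_element(bins: list[MaterialBin], mesh: FEMesh) -> np.ndarray:
    """Per-element bin index aligned with ``mesh.elem_ids``."""
    bid = {}
    for b in bins:
        for e in b.element_ids:
            bid[int(e)] = b.index
    try:
        return np.array([bid[int(e)] for e in mesh.elem_ids], dtype=np.int64)
    except KeyError as exc:
        raise BinningError(f"element {exc} not assigned to any bin") from None


def plot_distribution(bins: list[MaterialBin], path: str | Path | None = None):
    """Scatter of volume fraction vs representative modulus (one point per set)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = distribution_table(bins)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(df["E_repr_MPa"], df["volume_fraction"], "o", ms=4)
    ax.set_xlabel("Young's modulus, MPa")
    ax.set_ylabel("volume fraction")
    ax.set_title("material-set distribution")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return Path(path)
    return fig
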