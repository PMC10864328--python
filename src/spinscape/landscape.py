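"""Dynamic landscapes: per-site timescale/weight maps.

A "dynamic landscape" stacks the fitted exponential weights of many
sites (residues along a sequence, carbons along a detergent tail) into a
sites x timescales matrix, showing at a glance which motional timescales
dominate rotational relaxation where. For presentation the fine fitting
grid is usually coarsened by summing weights of a few (typically five)
consecutive timescales; the merged bin is represented by the geometric
mean of its members, preserving log-symmetry, and per-site total weight
is conserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectral import ExponentialFit

__all__ = [
    "Landscape",
    "assemble_landscape",
    "merge_consecutive",
    "dominant_timescale",
    "write_landscape_table",
]


@dataclass
class Landscape:
    """Sites x timescales weight matrix (possibly with merged bins)."""

    site_labels: list[str]
    taus: np.ndarray        # ps, increasing (bin representatives after merging)
    weights: np.ndarray     # (n_sites, n_taus), all >= 0

    def __post_init__(self) -> None:
        self.site_labels = list(self.site_labels)
        self.taus = np.asarray(self.taus, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape != (len(self.site_labels), self.taus.size):
            raise ValueError("weights must be a (n_sites, n_taus) matrix")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        if np.any(np.diff(self.taus) <= 0):
            raise ValueError("taus must be strictly increasing")


def assemble_landscape(fits: list[ExponentialFit],
                       labels: list[str] | None = None) -> Landscape:
    """Stack fits (sharing one grid) into a landscape, rows in given order."""
    if not fits:
        raise ValueError("no fits to assemble")
    grid = fits[0].grid
    for f in fits[1:]:
        if f.grid != grid:
            raise ValueError("all fits must share the same timescale grid")
    if labels is None:
        labels = [f.site_label for f in fits]
    if len(labels) != len(fits):
        raise ValueError("one label per fit required")
    return Landscape(labels, grid.taus.copy(), np.vstack([f.weights for f in fits]))


def merge_consecutive(ls: Landscape, k: int) -> Landscape:
    """Sum weights of k consecutive timescales into presentation bins.

    The merged bin's representative timescale is the geometric mean of
    its members; a trailing partial group is kept as its own bin. Total
    weight per site is unchanged (plain summation, no renormalization).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        return Landscape(ls.site_labels, ls.taus.copy(), ls.weights.copy())
    n = ls.taus.size
    starts = range(0, n, k)
    new_taus = np.array([np.exp(np.mean(np.log(ls.taus[s:s + k]))) for s in starts])
    new_w = np.column_stack([ls.weights[:, s:s + k].sum(axis=1) for s in starts])
    return Landscape(ls.site_labels, new_taus, new_w)


def dominant_timescale(fit: ExponentialFit, window: float = 0.5,
                       merge_k: int = 5) -> tuple[float, float]:
    """Dominant rotational timescale of one site and its local weight.

    The fit's weights are merged in groups of ``merge_k`` consecutive grid
    points; the weight-maximizing bin (ties broken toward the slowest bin,
    so the result is deterministic) provides the representative timescale
    (its geometric mean). The returned weight is the total unmerged weight
    within +- ``window``/2 decades of that timescale.
    """
    if not np.any(fit.weights > 0):
        raise ValueError("fit has all-zero weights")
    ls = merge_consecutive(
        Landscape([fit.site_label], fit.grid.taus.copy(), fit.weights[None, :]),
        merge_k)
    binw = ls.weights[0]
    # argmax on the reversed array -> slowest bin wins ties
    best = binw.size - 1 - int(np.argmax(binw[::-1]))
    tau_star = float(ls.taus[best])
    half = 10.0 ** (window / 2.0)
    mask = (fit.grid.taus >= tau_star / half) & (fit.grid.taus <= tau_star * half)
    return tau_star, float(fit.weights[mask].sum())


def write_landscape_table(ls: Landscape, path) -> None:
    """Long-format TSV (site, tau_ps, weight) suitable for bubble plots."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# spinscape dynamic landscape\n")
        fh.write("site\ttau_ps\tweight\n")
        for label, row in zip(ls.site_labels, ls.weights):
            for tau, w in zip(ls.taus, row):
                fh.write(f"{label}\t{tau:.9g}\t{w:.9g}\n")
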