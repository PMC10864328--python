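"""Secondary-structure propensities and their correlation with relaxation.

Helicity of a residue is the fraction of frames in which its DSSP code
belongs to the helix set (alpha, 3-10 and pi helices — {H, G, I} — by
default; the set is configurable since different studies count
differently). "Local environment helicity" smooths the per-residue
profile over the residue and its existing neighbours, reflecting that an
amide bond's dynamics feel the conformation of the surrounding turn of
helix rather than a single residue's code.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

from .trajectory_io import SSTrajectory, DSSP_ALPHABET

__all__ = [
    "HelicityProfile",
    "helicity_propensity",
    "local_environment_helicity",
    "pearson_with_p",
    "DEFAULT_HELIX_CODES",
]

DEFAULT_HELIX_CODES = frozenset("HGI")


@dataclass
class HelicityProfile:
    residue_labels: list[str]
    helicity: np.ndarray                 # per-residue fraction in [0,1]
    local_helicity: np.ndarray | None = None   # neighbour-averaged

    def __post_init__(self) -> None:
        self.residue_labels = list(self.residue_labels)
        self.helicity = np.asarray(self.helicity, dtype=float)
        if self.helicity.shape != (len(self.residue_labels),):
            raise ValueError("one helicity value per residue required")
        for arr in (self.helicity, self.local_helicity):
            if arr is not None and (np.any(arr < 0) or np.any(arr > 1)):
                raise ValueError("helicity fractions must lie in [0, 1]")
        if self.local_helicity is not None:
            self.local_helicity = np.asarray(self.local_helicity, dtype=float)


def helicity_propensity(ss: SSTrajectory,
                        helix_codes=DEFAULT_HELIX_CODES) -> HelicityProfile:
    """Per-residue fraction of frames whose DSSP code is in ``helix_codes``."""
    helix_codes = frozenset(helix_codes)
    if not helix_codes <= DSSP_ALPHABET:
        raise ValueError(f"helix codes outside DSSP alphabet: "
                         f"{sorted(helix_codes - DSSP_ALPHABET)}")
    if ss.n_frames == 0:
        raise ValueError("empty secondary-structure trajectory")
    is_helix = np.isin(ss.codes, list(helix_codes))
    return HelicityProfile(ss.residue_labels, is_helix.mean(axis=0))


def local_environment_helicity(profile: HelicityProfile) -> HelicityProfile:
    """Average each residue's helicity with its existing neighbours.

    Interior residues average over themselves and both neighbours;
    terminal residues over themselves and their single neighbour; a
    single-residue profile is returned unchanged. The operation is not
    idempotent for non-constant profiles — apply it once.
    """
    h = profile.helicity
    n = h.size
    if n == 0:
        raise ValueError("empty profile")
    local = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - 1), min(n, i + 2)
        local[i] = h[lo:hi].mean()
    return HelicityProfile(profile.residue_labels, h.copy(), local)


def pearson_with_p(x, y) -> tuple[float, float]:
    """Sample Pearson correlation and two-sided p-value.

    The p-value comes from the t-distribution with n-2 degrees of
    freedom. Constant inputs (undefined r) and fewer than 3 points are
    rejected.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r, p = scipy.stats.pearsonr(x, y)
    return float(r), float(p)
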