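"""Redfield relaxation rates from fitted spectral densities.

Given the multi-exponential spectral representation of a bond vector's
rotational dynamics, this module evaluates the standard Redfield
expressions for

* backbone amide 15N, relaxed by the 1H-15N dipolar coupling and the 15N
  chemical shift anisotropy (CSA), yielding T1, T2 and the heteronuclear
  NOE, and
* deuterium (2H) in C-D bonds, relaxed by the quadrupolar interaction
  (axially symmetric field gradient, asymmetry parameter 0), yielding T1
  and T2.

Normalization: the correlation functions here follow the C(0) = 1
convention, so the fitted J(omega) is five times the Lipari-Szabo
spectral density; the reduced density j(omega) = J(omega)/5 enters the
Redfield prefactors below. Cross-correlated (dipole-CSA interference)
relaxation is neglected.

The default physical constants are community-standard backbone/methylene
values (r_NH = 1.02 A, CSA = -170 ppm, quadrupolar coupling 167 kHz) and
can be overridden per call. Predictions scale as r_NH^-6 through the
dipolar coupling, so the bond-length choice matters at the few-percent
level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectral import ExponentialFit

__all__ = [
    "FieldSpec",
    "NucleusConstants",
    "RelaxationResult",
    "larmor_frequencies",
    "relaxation_15N",
    "relaxation_2H",
    "write_relaxation_table",
    "GAMMA_H",
    "GAMMA_N15",
    "GAMMA_D",
]

MU0_OVER_4PI = 1.0e-7          # T m / A
HBAR = 1.054571817e-34         # J s

GAMMA_H = 2.6752218744e8       # rad s^-1 T^-1, 1H
GAMMA_N15 = -2.7126e7          # rad s^-1 T^-1, 15N (negative)
GAMMA_D = 4.10663e7            # rad s^-1 T^-1, 2H


@dataclass(frozen=True)
class FieldSpec:
    """Spectrometer field stated as the 1H Larmor frequency in MHz."""

    proton_frequency: float    # MHz
    temperature: float = 310.0  # K, metadata only

    def __post_init__(self) -> None:
        if self.proton_frequency <= 0:
            raise ValueError("proton_frequency must be positive")

    @property
    def omega_H(self) -> float:
        """|1H angular Larmor frequency| in rad/s."""
        return 2.0 * np.pi * self.proton_frequency * 1.0e6


@dataclass(frozen=True)
class NucleusConstants:
    """Physical constants entering the Redfield prefactors.

    ``j_normalization`` links the package's J (C(0)=1 convention) to the
    reduced spectral density of the Redfield equations: j = J / 5.
    """

    gamma_H: float = GAMMA_H
    gamma_X: float = GAMMA_N15      # the relaxing nucleus; negative for 15N
    r_XH: float = 1.02              # bond length, Angstrom (15N branch)
    delta_sigma: float = -170.0     # CSA, ppm (15N branch)
    chi: float = 167.0e3            # quadrupolar coupling e^2qQ/h, Hz (2H branch)
    j_normalization: float = 5.0

    def __post_init__(self) -> None:
        if self.gamma_H == 0 or self.gamma_X == 0:
            raise ValueError("gyromagnetic ratios must be non-zero")
        if self.r_XH <= 0:
            raise ValueError("r_XH must be positive")

    def dipolar_coupling(self) -> float:
        """|d| = (mu0/4pi) hbar gamma_H |gamma_X| / r_XH^3, rad/s."""
        r_m = self.r_XH * 1.0e-10
        return MU0_OVER_4PI * HBAR * abs(self.gamma_H) * abs(self.gamma_X) / r_m**3


DEFAULT_15N = NucleusConstants()
DEFAULT_2H = NucleusConstants(gamma_X=GAMMA_D)


@dataclass
class RelaxationResult:
    """Relaxation observables for one site at one field."""

    site_label: str
    T1: float                   # s
    T2: float                   # s
    hetNOE: float | None        # dimensionless; None for 2H
    field: FieldSpec
    nucleus: str = "15N"

    def __post_init__(self) -> None:
        if self.T1 <= 0 or self.T2 <= 0:
            raise ValueError("relaxation times must be positive")


def larmor_frequencies(field: FieldSpec, nucleus: str,
                       constants: NucleusConstants | None = None) -> dict[str, float]:
    """Angular frequency magnitudes (rad/s) entering the Redfield equations.

    For 15N: omega_H, omega_X, omega_diff = omega_H - omega_X and
    omega_sum = omega_H + omega_X. For 2H: omega_X (= omega_D) and
    omega_2X = 2 omega_D. Signs of gyromagnetic ratios are carried
    separately (spectral densities are even in omega).
    """
    if nucleus == "15N":
        gamma_X = (constants or DEFAULT_15N).gamma_X
    elif nucleus == "2H":
        gamma_X = (constants or DEFAULT_2H).gamma_X
    else:
        raise ValueError(f"unknown nucleus {nucleus!r}; expected '15N' or '2H'")
    omega_H = field.omega_H
    omega_X = omega_H * abs(gamma_X / GAMMA_H)
    out = {"omega_H": omega_H, "omega_X": omega_X}
    if nucleus == "15N":
        out["omega_diff"] = omega_H - omega_X
        out["omega_sum"] = omega_H + omega_X
    else:
        out["omega_2X"] = 2.0 * omega_X
    return out


def _reduced_j(fit: ExponentialFit, norm: float):
    """Return j(omega_rad_per_s) in seconds, j = J/norm."""
    taus_s = fit.grid.taus * 1.0e-12
    weights = fit.weights

    def j(omega: float) -> float:
        return float(2.0 / norm * np.sum(
            weights * taus_s / (1.0 + (omega * taus_s) ** 2)))

    return j


def relaxation_15N(fit: ExponentialFit, field: FieldSpec,
                   constants: NucleusConstants = DEFAULT_15N) -> RelaxationResult:
    """15N T1, T2 and hetNOE from dipolar (1H-15N) and CSA relaxation.

    With d the dipolar coupling, c = omega_N * delta_sigma / sqrt(3) the
    CSA coupling and j(omega) the reduced spectral density:

        R1 = (d^2/4) [j(wH-wN) + 3 j(wN) + 6 j(wH+wN)] + c^2 j(wN)
        R2 = (d^2/8) [4 j(0) + j(wH-wN) + 3 j(wN) + 6 j(wH) + 6 j(wH+wN)]
             + (c^2/6) [4 j(0) + 3 j(wN)]
        NOE = 1 + (gamma_H/gamma_N) (d^2/4) [6 j(wH+wN) - j(wH-wN)] T1

    gamma_N < 0 makes the extreme-narrowing NOE negative and the
    slow-tumbling NOE approach 1 from below.
    """
    if not np.any(fit.weights > 0):
        raise ValueError("fit has all-zero weights")
    freqs = larmor_frequencies(field, "15N", constants)
    wH, wN = freqs["omega_H"], freqs["omega_X"]
    wd, ws = freqs["omega_diff"], freqs["omega_sum"]
    j = _reduced_j(fit, constants.j_normalization)
    d = constants.dipolar_coupling()
    c = wN * constants.delta_sigma * 1.0e-6 / np.sqrt(3.0)

    R1 = (d**2 / 4.0) * (j(wd) + 3.0 * j(wN) + 6.0 * j(ws)) + c**2 * j(wN)
    R2 = ((d**2 / 8.0) * (4.0 * j(0.0) + j(wd) + 3.0 * j(wN)
                          + 6.0 * j(wH) + 6.0 * j(ws))
          + (c**2 / 6.0) * (4.0 * j(0.0) + 3.0 * j(wN)))
    T1 = 1.0 / R1
    gamma_ratio = constants.gamma_H / constants.gamma_X  # signed
    noe = 1.0 + gamma_ratio * (d**2 / 4.0) * (6.0 * j(ws) - j(wd)) * T1
    return RelaxationResult(fit.site_label, T1, 1.0 / R2, noe, field, "15N")


def relaxation_2H(fit: ExponentialFit, field: FieldSpec,
                  constants: NucleusConstants = DEFAULT_2H) -> RelaxationResult:
    """Deuterium T1 and T2 from quadrupolar relaxation.

    With chi = e^2 q Q / h the quadrupolar coupling constant (Hz) and an
    axially symmetric field gradient:

        R1 = (3 pi^2 / 10) chi^2 [ j(wD) + 4 j(2 wD) ]
        R2 = (3 pi^2 / 20) chi^2 [ 3 j(0) + 5 j(wD) + 2 j(2 wD) ]
    """
    if not np.any(fit.weights > 0):
        raise ValueError("fit has all-zero weights")
    if constants.chi <= 0:
        raise ValueError("quadrupolar coupling chi must be positive")
    freqs = larmor_frequencies(field, "2H", constants)
    wD, w2D = freqs["omega_X"], freqs["omega_2X"]
    j = _reduced_j(fit, constants.j_normalization)
    chi2 = constants.chi**2

    R1 = (3.0 * np.pi**2 / 10.0) * chi2 * (j(wD) + 4.0 * j(w2D))
    R2 = (3.0 * np.pi**2 / 20.0) * chi2 * (3.0 * j(0.0) + 5.0 * j(wD) + 2.0 * j(w2D))
    return RelaxationResult(fit.site_label, 1.0 / R1, 1.0 / R2, None, field, "2H")


def write_relaxation_table(results: list[RelaxationResult], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# spinscape relaxation table\n")
        fh.write("site\tT1_s\tT2_s\thetNOE\n")
        for r in results:
            noe = f"{r.hetNOE:.9g}" if r.hetNOE is not None else "NA"
            fh.write(f"{r.site_label}\t{r.T1:.9g}\t{r.T2:.9g}\t{noe}\n")
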