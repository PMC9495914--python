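"""Multi-pool Bloch-McConnell simulation of CEST saturation.

The water signal attenuation measured in a CEST experiment is modelled by the
coupled Bloch equations of a water pool and one or more dilute exchanging
solute pools (here: the N-acetylcysteine thiol at -2.7 ppm and the glutathione
amide at +3.6 ppm), extended with first-order two-site exchange between each
solute and water.  The state of an ``N``-pool system is the stacked vector
``M = (Mx_1, My_1, Mz_1, ..., Mx_N, My_N, Mz_N)`` obeying

    dM/dt = A(offset, B1) M + b,

where ``A`` carries relaxation, off-resonance precession, the B1 coupling and
the exchange rates, and ``b`` carries the longitudinal recovery terms.
Exchange respects detailed balance: the water->solute rate is
``fraction * k_exch`` for a solute with back-rate ``k_exch``.

Two solvers are provided: the analytic continuous-wave steady state (the fixed
point of the linear system, used as an oracle) and a piecewise-constant
matrix-propagator integration of a shaped saturation pulse train, which is the
model of the acquisition actually used (a train of 30 ms Gaussian pulses, one
per radial readout spoke).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.linalg import expm

__all__ = [
    "GAMMA_HZ_PER_T",
    "Pool",
    "FieldParams",
    "SaturationPulse",
    "SaturationTrain",
    "ZSpectrum",
    "water_pool",
    "thiol_pool",
    "amide_pool",
    "build_exchange_matrix",
    "steady_state_cw",
    "simulate_pulse_train",
    "zspectrum",
    "mtr_profile",
]

#: Proton gyromagnetic ratio over 2*pi, Hz/T.  1 ppm = 298.04 Hz at 7 T.
GAMMA_HZ_PER_T = 42.577e6

#: Default reference offset used for S0 images, ppm.
S0_OFFSET_PPM = 333.0


@dataclass(frozen=True)
class Pool:
    """One proton species in the exchange model.

    Parameters
    ----------
    name:
        Label; the pool named ``"water"`` is the observed pool.
    delta_ppm:
        Chemical shift relative to water (water = 0; upfield negative, so the
        thiol sits at -2.7 ppm and the amide at +3.6 ppm).
    T1_s, T2_s:
        Longitudinal / transverse relaxation times in seconds.
    fraction:
        Proton fraction relative to water (water = 1).
    k_exch_per_s:
        Solute -> water exchange rate in 1/s (0 for water itself).
    """

    name: str
    delta_ppm: float
    T1_s: float
    T2_s: float
    fraction: float
    k_exch_per_s: float = 0.0

    def __post_init__(self) -> None:
        for attr in ("delta_ppm", "T1_s", "T2_s", "fraction", "k_exch_per_s"):
            if not np.isfinite(getattr(self, attr)):
                raise ValueError(f"pool {self.name!r}: {attr} must be finite")
        if self.T1_s <= 0 or self.T2_s <= 0:
            raise ValueError(f"pool {self.name!r}: relaxation times must be positive")
        if self.T2_s > self.T1_s:
            raise ValueError(f"pool {self.name!r}: T2 must not exceed T1")
        if self.fraction < 0:
            raise ValueError(f"pool {self.name!r}: fraction must be >= 0")
        if self.k_exch_per_s < 0:
            raise ValueError(f"pool {self.name!r}: exchange rate must be >= 0")
        if self.name == "water" and (self.delta_ppm != 0.0 or self.fraction != 1.0):
            raise ValueError("water pool must have delta_ppm = 0 and fraction = 1")


def water_pool(T1_s: float = 1.8, T2_s: float = 0.030) -> Pool:
    """Liver water at 7 T (placeholder relaxation values, see docs)."""
    return Pool("water", 0.0, T1_s, T2_s, 1.0, 0.0)


def thiol_pool(fraction: float = 2e-4, k_exch_per_s: float = 1000.0,
               T1_s: float = 1.0, T2_s: float = 0.020) -> Pool:
    """NAC thiol proton pool at -2.7 ppm (placeholder kinetics, see docs)."""
    return Pool("thiol", -2.7, T1_s, T2_s, fraction, k_exch_per_s)


def amide_pool(fraction: float = 2e-4, k_exch_per_s: float = 30.0,
               T1_s: float = 1.0, T2_s: float = 0.020) -> Pool:
    """GSH amide proton pool at +3.6 ppm (placeholder kinetics, see docs)."""
    return Pool("amide", 3.6, T1_s, T2_s, fraction, k_exch_per_s)


@dataclass(frozen=True)
class FieldParams:
    """Static-field description.  ppm -> Hz uses gamma_hz_per_T * B0_T * 1e-6."""

    B0_T: float = 7.0
    gamma_hz_per_T: float = GAMMA_HZ_PER_T
    drift_hz_per_min: float = 0.0

    def __post_init__(self) -> None:
        if self.B0_T <= 0:
            raise ValueError("B0_T must be positive")
        if self.gamma_hz_per_T <= 0:
            raise ValueError("gamma_hz_per_T must be positive")

    @property
    def hz_per_ppm(self) -> float:
        return self.gamma_hz_per_T * self.B0_T * 1e-6

    def ppm_to_hz(self, ppm: float) -> float:
        return ppm * self.hz_per_ppm

    def drift_ppm_at(self, t_min: float) -> float:
        """Accumulated B0 drift at time ``t_min``, expressed in ppm."""
        return self.drift_hz_per_min * t_min / self.hz_per_ppm


@dataclass(frozen=True)
class SaturationPulse:
    """Saturation RF pulse: continuous-wave, rectangular or Gaussian envelope.

    ``truncation_sigma`` is the Gaussian half-width in standard deviations, so
    the envelope spans ``duration_s = 2 * truncation_sigma * sigma``; the
    default +-2.5 sigma puts sigma at duration/5.
    """

    shape: str = "gaussian"
    b1_peak_uT: float = 1.2
    duration_s: float = 0.030
    truncation_sigma: float = 2.5

    def __post_init__(self) -> None:
        if self.shape not in ("cw", "block", "gaussian"):
            raise ValueError(f"unknown pulse shape {self.shape!r}")
        if self.b1_peak_uT < 0:
            raise ValueError("b1_peak_uT must be >= 0")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.truncation_sigma <= 0:
            raise ValueError("truncation_sigma must be positive")

    def envelope(self, n_sub: int) -> np.ndarray:
        """Midpoint-sampled B1 amplitudes (uT) for ``n_sub`` equal sub-steps."""
        if self.shape in ("cw", "block"):
            return np.full(n_sub, self.b1_peak_uT)
        t = (np.arange(n_sub) + 0.5) / n_sub  # in (0, 1)
        sigma = 1.0 / (2.0 * self.truncation_sigma)  # in units of the duration
        return self.b1_peak_uT * np.exp(-0.5 * ((t - 0.5) / sigma) ** 2)

    @property
    def b1_rms_uT(self) -> float:
        """Root-mean-square amplitude of the envelope over the pulse."""
        if self.shape in ("cw", "block"):
            return self.b1_peak_uT
        env = self.envelope(512)
        return float(np.sqrt(np.mean(env**2)))

    def as_equivalent_cw(self) -> "SaturationPulse":
        """CW pulse with the same average power (B1,rms) as this envelope."""
        return replace(self, shape="cw", b1_peak_uT=self.b1_rms_uT)


@dataclass(frozen=True)
class SaturationTrain:
    """A train of identical saturation pulses separated by free relaxation.

    The acquisition interleaves one pulse per radial spoke; with 302 spokes of
    30 ms pulses the total saturation time per offset is 30 ms x 302 = 9.06 s.
    """

    pulse: SaturationPulse
    n_pulses: int = 302
    interpulse_delay_s: float = 0.01041

    def __post_init__(self) -> None:
        if self.n_pulses < 1:
            raise ValueError("n_pulses must be >= 1")
        if self.interpulse_delay_s < 0:
            raise ValueError("interpulse_delay_s must be >= 0")

    @property
    def total_saturation_s(self) -> float:
        return self.n_pulses * self.pulse.duration_s

    @property
    def total_elapsed_s(self) -> float:
        return self.n_pulses * (self.pulse.duration_s + self.interpulse_delay_s)


@dataclass
class ZSpectrum:
    """Normalized water signal S/S0 versus saturation offset from water."""

    offsets_ppm: np.ndarray
    z_values: np.ndarray
    reference_offset_ppm: float = S0_OFFSET_PPM

    def __post_init__(self) -> None:
        self.offsets_ppm = np.asarray(self.offsets_ppm, dtype=float)
        self.z_values = np.asarray(self.z_values, dtype=float)
        if self.offsets_ppm.shape != self.z_values.shape:
            raise ValueError("offsets and z_values must have equal length")


def _validate_pools(pools: Sequence[Pool]) -> int:
    """Return the index of the single water pool, raising otherwise."""
    water_idx = [i for i, p in enumerate(pools) if p.name == "water"]
    if not water_idx:
        raise ValueError("pool list must contain a pool named 'water'")
    if len(water_idx) > 1:
        raise ValueError("pool list must contain exactly one water pool")
    return water_idx[0]


def build_exchange_matrix(
    pools: Sequence[Pool],
    offset_ppm: float,
    b1_uT: float,
    field: FieldParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Rate matrix ``A`` and recovery vector ``b`` of the coupled system.

    Each pool contributes a 3x3 block over its (Mx, My, Mz) components; solute
    pools exchange with water only (star topology).  Returns ``(A, b)`` with
    ``A`` of dimension ``3 * len(pools)``.
    """
    iw = _validate_pools(pools)
    if not np.isfinite(offset_ppm) or not np.isfinite(b1_uT):
        raise ValueError("offset and B1 must be finite")
    n = len(pools)
    omega1 = 2.0 * np.pi * field.gamma_hz_per_T * b1_uT * 1e-6  # rad/s
    A = np.zeros((3 * n, 3 * n))
    b = np.zeros(3 * n)
    for i, p in enumerate(pools):
        dw = 2.0 * np.pi * field.ppm_to_hz(p.delta_ppm - offset_ppm)  # rad/s
        r1, r2 = 1.0 / p.T1_s, 1.0 / p.T2_s
        s = 3 * i
        A[s + 0, s + 0] = -r2
        A[s + 0, s + 1] = -dw
        A[s + 1, s + 0] = dw
        A[s + 1, s + 1] = -r2
        A[s + 1, s + 2] = omega1
        A[s + 2, s + 1] = -omega1
        A[s + 2, s + 2] = -r1
        b[s + 2] = r1 * p.fraction
    sw = 3 * iw
    for i, p in enumerate(pools):
        if i == iw:
            continue
        k_sw = p.k_exch_per_s          # solute -> water
        k_ws = p.fraction * k_sw       # water -> solute (detailed balance)
        s = 3 * i
        for c in range(3):
            A[sw + c, sw + c] -= k_ws
            A[s + c, s + c] -= k_sw
            A[sw + c, s + c] += k_sw
            A[s + c, sw + c] += k_ws
    return A, b


def equilibrium_state(pools: Sequence[Pool]) -> np.ndarray:
    """Thermal equilibrium magnetization vector (Mz_i = fraction_i)."""
    _validate_pools(pools)
    m = np.zeros(3 * len(pools))
    m[2::3] = [p.fraction for p in pools]
    return m


def steady_state_cw(
    pools: Sequence[Pool],
    offset_ppm: float,
    b1_uT: float,
    field: FieldParams,
) -> float:
    """Water Z value of the continuous-wave steady state.

    Solves the fixed point ``A M + b = 0`` of the linear Bloch-McConnell
    system; serves as the analytic oracle for the pulse-train integrator.
    """
    if b1_uT < 0:
        raise ValueError("b1_uT must be >= 0")
    iw = _validate_pools(pools)
    A, b = build_exchange_matrix(pools, offset_ppm, b1_uT, field)
    try:
        m = np.linalg.solve(A, -b)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - pathological
        raise ValueError("singular Bloch-McConnell system") from exc
    if not np.all(np.isfinite(m)):
        raise ValueError("singular Bloch-McConnell system")
    return float(m[3 * iw + 2])


def _affine_propagator(A: np.ndarray, b: np.ndarray, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Exact affine map M -> E M + w for dM/dt = A M + b over a step dt."""
    E = expm(A * dt)
    x = np.linalg.solve(A, b)
    w = E @ x - x
    return E, w


def simulate_pulse_train(
    pools: Sequence[Pool],
    train: SaturationTrain,
    offset_ppm: float,
    field: FieldParams,
    initial_state: np.ndarray | None = None,
    substep_s: float = 1e-4,
    readout_flip_deg: float = 0.0,
) -> float:
    """Water Z after a full shaped-pulse saturation train.

    The pulse envelope is discretized into equal sub-steps of at most
    ``substep_s``; each sub-step and each interpulse gap is propagated with the
    exact matrix exponential of the piecewise-constant system, so the only
    discretization error is the envelope staircase (testable by halving the
    sub-step).  ``readout_flip_deg`` optionally scales all longitudinal
    components by cos(flip) after each pulse (crushed-transverse readout
    excitation); default off.
    """
    iw = _validate_pools(pools)
    if substep_s <= 0:
        raise ValueError("substep_s must be positive")
    if substep_s > train.pulse.duration_s:
        raise ValueError("integration sub-step larger than the pulse duration")
    n = 3 * len(pools)
    if train.pulse.shape in ("cw", "block"):
        n_sub = 1
    else:
        n_sub = int(np.ceil(train.pulse.duration_s / substep_s))
    dt = train.pulse.duration_s / n_sub
    env = train.pulse.envelope(n_sub)

    # Compose the affine map of one pulse (+ optional readout, + gap).
    P = np.eye(n)
    q = np.zeros(n)
    unique_b1, inverse = np.unique(env, return_inverse=True)
    props = [_affine_propagator(*build_exchange_matrix(pools, offset_ppm, b1, field), dt)
             for b1 in unique_b1]
    for j in inverse:
        E, w = props[j]
        P = E @ P
        q = E @ q + w
    if readout_flip_deg:
        R = np.zeros((n, n))
        R[2::3, 2::3] = np.eye(len(pools)) * np.cos(np.deg2rad(readout_flip_deg))
        P = R @ P
        q = R @ q
    if train.interpulse_delay_s > 0:
        A0, b0 = build_exchange_matrix(pools, offset_ppm, 0.0, field)
        E, w = _affine_propagator(A0, b0, train.interpulse_delay_s)
        P = E @ P
        q = E @ q + w

    m0 = equilibrium_state(pools) if initial_state is None else np.asarray(initial_state, float)
    # M_N = P^N M0 + (I - P)^-1 (I - P^N) q
    PN = np.linalg.matrix_power(P, train.n_pulses)
    geo = np.linalg.solve(np.eye(n) - P, (np.eye(n) - PN) @ q)
    m = PN @ m0 + geo
    return float(m[3 * iw + 2])


def zspectrum(
    pools: Sequence[Pool],
    offsets_ppm: Iterable[float],
    scheme: SaturationTrain,
    field: FieldParams,
    substep_s: float = 1e-4,
    readout_flip_deg: float = 0.0,
) -> ZSpectrum:
    """Z-spectrum from independent pulse-train simulations at each offset.

    Every offset starts from thermal equilibrium, matching an acquisition in
    which each image's 9.06 s saturation block drives its own steady state.
    """
    offsets = np.atleast_1d(np.asarray(list(offsets_ppm), dtype=float))
    if offsets.size == 0:
        raise ValueError("offset list must not be empty")
    if not np.all(np.isfinite(offsets)):
        raise ValueError("offsets must be finite")
    z = np.array([
        simulate_pulse_train(pools, scheme, w, field,
                             substep_s=substep_s, readout_flip_deg=readout_flip_deg)
        for w in offsets
    ])
    return ZSpectrum(offsets, z)


def mtr_profile(z_without: ZSpectrum, z_with: ZSpectrum) -> np.ndarray:
    """Per-offset MTR(w) = Z_without(w) - Z_with(w) on a common offset grid."""
    if z_with.offsets_ppm.shape != z_without.offsets_ppm.shape or not np.allclose(
        z_with.offsets_ppm, z_without.offsets_ppm
    ):
        raise ValueError("Z-spectra must share the same offset grid")
    return z_without.z_values - z_with.z_values
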