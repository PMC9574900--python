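"""Linearized spectral oracle for a single corticothalamic unit.

The model is linearized about its fixed point; each population's dendritic
filter becomes ``L(w) = 1/((1 + iw/alpha)(1 + iw/beta))``, the cortical
excitatory axonal dynamics become ``A(w) = 1/(1 + iw/gamma)^2`` and every
corticothalamic leg contributes a delay factor ``exp(-iw t0/2)``.  Solving
the resulting 4x4 linear system for the noise-to-phi_e transfer function
gives a closed-form prediction of the simulated power spectral density,
independent of the time-stepping code, so it serves as a verification
oracle for the integrator.
"""

from __future__ import annotations

import numpy as np

from .errors import LinearInstabilityError
from .metrics import SpectrumEstimate
from .model import steady_state
from .params import CorticothalamicParams, firing_rate_slope

__all__ = [
    "linear_spectrum",
    "unit_transfer",
    "rhp_winding_number",
    "welch_expected_psd",
]

_POPULATIONS = ("phi_e", "V_e", "V_i", "V_r", "V_s")


def _scaled_couplings(params: CorticothalamicParams, coupling_scales):
    from .perturbation import apply_reduction  # local import; no cycle at load

    s_e, s_i = (float(x) for x in coupling_scales)
    return apply_reduction(params.couplings, s_e, s_i)


def _system_matrices(params, nu, rho, omega, extra_ee=0.0):
    """Return (M, b) of M x = b phi_n for x = [V_e, V_i, V_r, V_s]."""
    w = np.atleast_1d(np.asarray(omega, dtype=float))
    L_inv = (1 + 1j * w / params.alpha_d) * (1 + 1j * w / params.beta_d)
    A = 1.0 / (1 + 1j * w / params.gamma_e) ** 2
    E = np.exp(-1j * w * params.t0 / 2.0)
    rho_e, rho_i, rho_r, rho_s = rho
    m = np.zeros((w.size, 4, 4), dtype=complex)
    ge = (nu.nu_ee + extra_ee) * A * rho_e
    m[:, 0, 0] = L_inv - ge
    m[:, 0, 1] = -nu.nu_ei * rho_i
    m[:, 0, 3] = -nu.nu_es * rho_s * E
    m[:, 1, 0] = -nu.nu_ie * A * rho_e
    m[:, 1, 1] = L_inv - nu.nu_ii * rho_i
    m[:, 1, 3] = -nu.nu_is * rho_s * E
    m[:, 2, 0] = -nu.nu_re * A * rho_e * E
    m[:, 2, 2] = L_inv
    m[:, 2, 3] = -nu.nu_rs * rho_s
    m[:, 3, 0] = -nu.nu_se * A * rho_e * E
    m[:, 3, 2] = -nu.nu_sr * rho_r
    m[:, 3, 3] = L_inv
    b = np.zeros((w.size, 4), dtype=complex)
    b[:, 3] = nu.nu_sn
    return m, b, A, L_inv


def rhp_winding_number(
    params: CorticothalamicParams,
    coupling_scales=(1.0, 1.0),
    f_max: float = 500.0,
    n_grid: int = 200_001,
    extra_ee: float = 0.0,
) -> int:
    """Winding number of the characteristic function around 0 (Nyquist test).

    ``G(w) = det(M(w)) / L_inv(w)^4`` is analytic in the growth half-plane
    and tends to 1 at large |w|, so a nonzero winding of G along the real
    frequency axis counts unstable linear modes.
    """
    nu = _scaled_couplings(params, coupling_scales)
    p = params.replace(couplings=nu)
    fp = steady_state(p, extra_ee_gain=extra_ee)
    rho = tuple(firing_rate_slope(v, p) for v in fp.as_array())
    w = np.linspace(-2 * np.pi * f_max, 2 * np.pi * f_max, n_grid)
    m, _, _, L_inv = _system_matrices(p, nu, rho, w, extra_ee)
    g = np.linalg.det(m) / L_inv**4
    phase = np.unwrap(np.angle(g))
    return int(np.round((phase[-1] - phase[0]) / (2 * np.pi)))


def unit_transfer(
    params: CorticothalamicParams,
    coupling_scales=(1.0, 1.0),
    freqs=None,
    extra_ee: float = 0.0,
) -> dict[str, np.ndarray]:
    """Complex noise-to-state transfer functions of one linearized unit.

    Returns a dict with keys ``phi_e, V_e, V_i, V_r, V_s`` mapping to the
    transfer from the external drive phi_n to that variable, evaluated on
    ``freqs`` (Hz).
    """
    freqs = np.asarray(freqs, dtype=float)
    nu = _scaled_couplings(params, coupling_scales)
    p = params.replace(couplings=nu)
    fp = steady_state(p, extra_ee_gain=extra_ee)
    rho = tuple(firing_rate_slope(v, p) for v in fp.as_array())
    omega = 2 * np.pi * freqs
    m, b, A, _ = _system_matrices(p, nu, rho, omega, extra_ee)
    x = np.linalg.solve(m, b[..., None])[..., 0]
    out = {
        "V_e": x[:, 0],
        "V_i": x[:, 1],
        "V_r": x[:, 2],
        "V_s": x[:, 3],
        "phi_e": A * rho[0] * x[:, 0],
    }
    return out


def welch_expected_psd(
    params: CorticothalamicParams,
    freqs_out,
    fs: float,
    window_s: float,
    coupling_scales=(1.0, 1.0),
    population: str = "phi_e",
    extra_ee: float = 0.0,
) -> SpectrumEstimate:
    """Expected Welch PSD of the linearized unit under a Hann window.

    The analytic spectrum can be much narrower than the Welch frequency
    resolution, so an unbiased comparison convolves it with the window's
    spectral power kernel before sampling at the Welch bins.  Valid away
    from 0 Hz and Nyquist (no edge folding).
    """
    freqs_out = np.asarray(freqs_out, dtype=float)
    df = 1.0 / (16.0 * window_s)
    half_span = 6.0  # Hz of kernel support kept on each side
    fine = np.arange(
        max(df, freqs_out[0] - half_span),
        min(fs / 2.0 - df, freqs_out[-1] + half_span),
        df,
    )
    psd_fine = linear_spectrum(
        params, coupling_scales, fine, population=population,
        check_stability=False, extra_ee=extra_ee,
    ).psd[0]
    n_win = int(round(window_s * fs))
    w = np.hanning(n_win)
    n_fft = int(2 ** np.ceil(np.log2(n_win * 16)))
    wf = np.fft.rfft(w, n_fft)
    k_freqs = np.fft.rfftfreq(n_fft, d=1.0 / fs)
    kernel = np.abs(wf) ** 2
    keep = k_freqs <= half_span
    # symmetric kernel on the fine grid, unit integral
    k_half = np.interp(np.arange(0.0, half_span, df), k_freqs[keep],
                       kernel[keep])
    k_sym = np.concatenate([k_half[:0:-1], k_half])
    k_sym /= k_sym.sum()
    smoothed = np.convolve(psd_fine, k_sym, mode="same")
    out = np.interp(freqs_out, fine, smoothed)
    return SpectrumEstimate(
        freqs=freqs_out, psd=out[None, :], window_s=window_s, overlap=0.5
    )


def linear_spectrum(
    params: CorticothalamicParams,
    coupling_scales=(1.0, 1.0),
    freqs=None,
    population: str = "phi_e",
    check_stability: bool = True,
    extra_ee: float = 0.0,
) -> SpectrumEstimate:
    """Predicted one-sided PSD of ``population`` for one unit.

    The absolute scale assumes the discrete white-noise convention of the
    integrator (``phi_n`` spectral density ``noise_std**2``), so at low
    noise the prediction matches a Welch estimate of the simulated unit up
    to estimation error.

    Raises
    ------
    LinearInstabilityError
        If the linearization has a pole in the growth half-plane.
    """
    if freqs is None:
        freqs = np.linspace(0.25, 45.0, 180)
    freqs = np.asarray(freqs, dtype=float)
    if population not in _POPULATIONS:
        raise ValueError(f"population must be one of {_POPULATIONS}")
    if check_stability:
        winding = rhp_winding_number(params, coupling_scales, extra_ee=extra_ee)
        if winding != 0:
            raise LinearInstabilityError(
                f"linearized unit has {winding} pole(s) in the growth half-plane"
            )
    t = unit_transfer(params, coupling_scales, freqs, extra_ee)[population]
    psd = 2.0 * params.noise_std**2 * np.abs(t) ** 2
    return SpectrumEstimate(
        freqs=freqs, psd=psd[None, :], window_s=np.inf, overlap=0.0
    )
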