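"""Per-replicate fluorescence estimation from 8-gate cell counts.

A sorted replicate's cells are assumed log10-normally distributed; the
observed cell counts across gates are least-squares fitted to the integral of
a normal density over each gate's (possibly open-ended) log10-fluorescence
bounds.  Estimates from the second sorter are mapped onto the first sorter's
scale by linear regression over shared wildtype genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.special import ndtr

from .simulate import GateScheme

SIGMA_BOUNDS = (0.005, 2.0)


@dataclass
class FluorEstimate:
    mu: float
    sigma: float
    n_cells: float
    fit_ok: bool
    message: str = ""


@dataclass
class MachineCalibration:
    """Linear map from sorter-B fluorescence onto the sorter-A scale."""

    slope: float
    intercept: float
    n_anchors: int

    def apply(self, estimate: FluorEstimate) -> FluorEstimate:
        return FluorEstimate(
            mu=self.slope * estimate.mu + self.intercept,
            sigma=abs(self.slope) * estimate.sigma,
            n_cells=estimate.n_cells,
            fit_ok=estimate.fit_ok,
            message=estimate.message,
        )


def _gate_edges(boundaries: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lo = np.concatenate(([-np.inf], boundaries))
    hi = np.concatenate((boundaries, [np.inf]))
    return lo, hi


def fit_gate_distribution(counts: np.ndarray, gates: GateScheme) -> FluorEstimate:
    """Fit (μ, σ, N) of a gated normal to an 8-gate cell-count vector.

    Model: counts[g] ≈ N · (Φ((hi_g−μ)/σ) − Φ((lo_g−μ)/σ)).  The initial μ is
    the center of the gate with the highest count, the initial σ that gate's
    width (open-ended gates borrow the adjacent inner gate's width).  σ
    collapsing onto its bounds, or optimizer failure, flags the fit as bad.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (8,):
        raise ValueError("counts must be a vector over the 8 gates")
    total = counts.sum()
    if total <= 0:
        raise ValueError("total cells must be positive")

    b = np.asarray(gates.boundaries, dtype=float)
    lo, hi = _gate_edges(b)
    widths = np.diff(b)
    g_max = int(np.argmax(counts))
    inner_width = widths[min(max(g_max - 1, 0), len(widths) - 1)]
    if g_max == 0:
        mu0, sig0 = b[0] - inner_width / 2, inner_width
    elif g_max == 7:
        mu0, sig0 = b[-1] + inner_width / 2, inner_width
    else:
        mu0, sig0 = 0.5 * (b[g_max - 1] + b[g_max]), b[g_max] - b[g_max - 1]

    mu_lo, mu_hi = b[0] - 2.0, b[-1] + 2.0

    inv_sqrt2pi = 1.0 / np.sqrt(2.0 * np.pi)

    def residuals(params):
        mu, sigma, n = params
        p = ndtr((hi - mu) / sigma) - ndtr((lo - mu) / sigma)
        return n * p - counts

    def jacobian(params):
        mu, sigma, n = params
        z_hi = (hi - mu) / sigma
        z_lo = (lo - mu) / sigma
        p = ndtr(z_hi) - ndtr(z_lo)
        phi_hi = np.where(np.isfinite(z_hi), np.exp(-0.5 * z_hi**2) * inv_sqrt2pi, 0.0)
        phi_lo = np.where(np.isfinite(z_lo), np.exp(-0.5 * z_lo**2) * inv_sqrt2pi, 0.0)
        d_mu = -n / sigma * (phi_hi - phi_lo)
        zphi_hi = np.where(np.isfinite(z_hi), z_hi, 0.0) * phi_hi
        zphi_lo = np.where(np.isfinite(z_lo), z_lo, 0.0) * phi_lo
        d_sigma = -n / sigma * (zphi_hi - zphi_lo)
        return np.column_stack((d_mu, d_sigma, p))

    try:
        res = optimize.least_squares(
            residuals,
            x0=[mu0, sig0, total],
            jac=jacobian,
            bounds=([mu_lo, SIGMA_BOUNDS[0], 1e-9], [mu_hi, SIGMA_BOUNDS[1], np.inf]),
            x_scale=[1.0, 0.3, max(total, 1.0)],
            ftol=1e-6,
            xtol=1e-6,
        )
    except Exception as exc:  # pragma: no cover - optimizer pathologies
        return FluorEstimate(np.nan, np.nan, total, False, f"optimizer error: {exc}")

    mu, sigma, n = res.x
    ok = bool(res.success)
    msg = ""
    if not ok:
        msg = "optimizer did not converge"
    elif sigma <= SIGMA_BOUNDS[0] * 1.2 or sigma >= SIGMA_BOUNDS[1] * 0.99:
        ok, msg = False, "sigma collapsed to bound"
    return FluorEstimate(float(mu), float(sigma), float(total), ok, msg)


def calibrate_machines(
    estimates_a: dict[object, FluorEstimate],
    estimates_b: dict[object, FluorEstimate],
    shared_wildtype_ids: list[object],
) -> MachineCalibration:
    """OLS of sorter-A fluorescence on sorter-B over shared wildtype anchors."""
    xs, ys = [], []
    for key in shared_wildtype_ids:
        ea, eb = estimates_a.get(key), estimates_b.get(key)
        if ea is None or eb is None or not (ea.fit_ok and eb.fit_ok):
            continue
        xs.append(eb.mu)
        ys.append(ea.mu)
    if len(xs) < 2:
        raise ValueError(f"need ≥2 wildtype anchors with good fits, got {len(xs)}")
    fit = stats.linregress(xs, ys)
    if fit.slope <= 0:
        raise ValueError("calibration slope must be positive")
    return MachineCalibration(float(fit.slope), float(fit.intercept), len(xs))
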