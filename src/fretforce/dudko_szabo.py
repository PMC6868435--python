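"""Dudko-Szabo force-dependent rupture kinetics.

Rate law, rupture-force distributions under a loading schedule,
stochastic sampling, censored maximum-likelihood mixture fitting, and
force-profile reconstruction.

The unfolding rate under force follows the microscopic Dudko-Hummer-
Szabo form

    k(F) = (1/tau0) * (1 - nu F dx/ dG_E)^(1/nu - 1)
           * exp{ dG * [1 - (1 - nu F dx / dG_E)^(1/nu)] },

with dG_E = dG * kBT, transition-state distance dx (nm), zero-force
lifetime tau0 (s) and activation free energy dG (in kBT).  nu = 1/2
(cusp-shaped barrier) is the pipeline default; nu = 1 recovers the Bell
model exactly and nu = 2/3 (linear-cubic) is available for sensitivity
checks.  The barrier vanishes at the critical force
F_c = dG kBT / (nu dx).

Under a loading schedule the rupture-force density is

    p(F) = [k(F)/Fdot(F)] * exp(- int_{F_start}^{F} k(f)/Fdot(f) df).

``rate_mode`` selects the loading-rate convention: ``"effective"``
(default) uses the schedule's force-averaged constant rate, matching
the standard constant-loading-rate Dudko-Szabo treatment of rupture
histograms; ``"instantaneous"`` uses the full nonlinear Fdot(F) of the
tether; a float uses that constant rate directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .core_io import KBT_ROOM, InsufficientDataError
from .tether_mechanics import LoadingSchedule

__all__ = [
    "DsParams",
    "DsMixture",
    "RuptureSample",
    "RuptureSamples",
    "RuptureDensity",
    "DsFit",
    "ds_rate",
    "rupture_pdf",
    "sample_ruptures",
    "fit_ds",
    "reconstruct_profile",
]


@dataclass(frozen=True)
class DsParams:
    """Kinetic parameters of one unfolding pathway."""

    dx_dagger: float  # nm
    tau0: float  # s, zero-force unfolding lifetime
    dG_dagger: float  # activation free energy in units of kBT
    nu: float = 0.5

    def __post_init__(self) -> None:
        if not (self.dx_dagger > 0 and self.tau0 > 0 and self.dG_dagger > 0):
            raise ValueError("dx_dagger, tau0 and dG_dagger must be positive")
        if self.nu not in (0.5, 2.0 / 3.0, 1.0):
            raise ValueError("nu must be one of 1/2, 2/3, 1")

    def critical_force(self, kBT: float = KBT_ROOM) -> float:
        """Force (pN) at which the activation barrier vanishes."""
        return self.dG_dagger * kBT / (self.nu * self.dx_dagger)


@dataclass(frozen=True)
class DsMixture:
    """Weighted mixture of Dudko-Szabo pathways (force clusters)."""

    components: tuple[DsParams, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.components) < 1 or len(self.components) != len(self.weights):
            raise ValueError("need >= 1 component with matching weights")
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be >= 0 and sum to 1 (tol 1e-9)")


def _as_mixture(p: DsParams | DsMixture) -> DsMixture:
    if isinstance(p, DsParams):
        return DsMixture(components=(p,), weights=(1.0,))
    return p


@dataclass(frozen=True)
class RuptureSample:
    """One pulling cycle's outcome: a rupture force or censoring at F_max."""

    force: float | None
    censored: bool = False


@dataclass
class RuptureSamples:
    """Collection of rupture forces plus right-censored cycle count."""

    forces: np.ndarray
    n_censored: int = 0
    f_max: float = np.inf
    component_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.forces = np.asarray(self.forces, dtype=float)
        if np.any(self.forces <= 0) or np.any(self.forces > self.f_max):
            raise ValueError("uncensored forces must lie in (0, f_max]")

    def __len__(self) -> int:
        return len(self.forces) + self.n_censored

    def to_list(self) -> list[RuptureSample]:
        out = [RuptureSample(force=float(f)) for f in self.forces]
        out += [RuptureSample(force=None, censored=True)] * self.n_censored
        return out


def ds_rate(F, p: DsParams, kBT: float = KBT_ROOM):
    """Unfolding rate k(F) in 1/s; valid for 0 <= F < F_c.

    Numerically stable special cases: nu = 1 evaluates the exact Bell
    exponent F*dx/kBT; nu = 1/2 expands 1 - (1-u)^2 = u(2-u).
    """
    F = np.asarray(F, dtype=float)
    scalar = F.ndim == 0
    Fv = np.atleast_1d(F)
    fc = p.critical_force(kBT)
    if np.any(Fv < 0) or np.any(Fv >= fc):
        raise ValueError(
            f"force out of Dudko-Szabo domain [0, F_c); F_c = {fc:.4g} pN "
            f"for dx={p.dx_dagger} nm, dG={p.dG_dagger} kBT, nu={p.nu}"
        )
    u = p.nu * Fv * p.dx_dagger / (p.dG_dagger * kBT)
    if p.nu == 1.0:
        k = np.exp(Fv * p.dx_dagger / kBT) / p.tau0
    elif p.nu == 0.5:
        k = (1.0 - u) * np.exp(p.dG_dagger * u * (2.0 - u)) / p.tau0
    else:
        inv = 1.0 / p.nu
        k = (1.0 - u) ** (inv - 1.0) * np.exp(p.dG_dagger * (1.0 - (1.0 - u) ** inv)) / p.tau0
    return float(k[0]) if scalar else k


def _rate_callable(schedule: LoadingSchedule, rate_mode):
    """Resolve the loading-rate convention into a vectorized Fdot(F)."""
    if rate_mode == "effective":
        r = schedule.effective_rate
        return lambda F: np.full_like(np.asarray(F, dtype=float), r)
    if rate_mode == "instantaneous":
        return lambda F: np.asarray(schedule.rate_of_force(F), dtype=float)
    if np.isscalar(rate_mode) and rate_mode > 0:
        r = float(rate_mode)
        return lambda F: np.full_like(np.asarray(F, dtype=float), r)
    raise ValueError(f"rate_mode must be 'effective', 'instantaneous' or a positive number, got {rate_mode!r}")


def _hazard_grid(
    p: DsParams,
    schedule: LoadingSchedule,
    kBT: float,
    rate_mode,
    n_grid: int,
):
    """Force grid, cumulative hazard H and survival S for one component.

    The grid spans [F_lo, min(F_max, F_c)); hazard accumulates from the
    schedule's starting force (0 for an idealized constant ramp).
    """
    fc = p.critical_force(kBT)
    f_lo = max(schedule.f_start, 0.0)
    f_hi = min(schedule.f_max, fc * (1.0 - 1e-9))
    if f_hi <= f_lo:
        raise ValueError(
            f"critical force {fc:.3g} pN is below the schedule start {f_lo:.3g} pN"
        )
    g = np.linspace(f_lo, f_hi, n_grid)
    rate = _rate_callable(schedule, rate_mode)
    h = ds_rate(g, p, kBT) / rate(g)
    dH = 0.5 * (h[1:] + h[:-1]) * np.diff(g)
    H = np.concatenate([[0.0], np.cumsum(dH)])
    return g, h, H


@dataclass
class RuptureDensity:
    """Tabulated rupture-force density under a loading schedule.

    ``survival`` is the probability of no rupture by the end of the
    usable force range (F_max, or F_c for components whose barrier
    vanishes inside the ramp; any such truncation is reported in
    ``component_survival``).
    """

    grid: np.ndarray
    pdf: np.ndarray
    survival: float
    f_start: float
    f_max: float
    component_survival: tuple[float, ...] = field(default_factory=tuple)
    component_fc: tuple[float, ...] = field(default_factory=tuple)

    def mode(self) -> float:
        """Modal rupture force, refined by a local parabolic fit."""
        i = int(np.argmax(self.pdf))
        if 0 < i < len(self.grid) - 1:
            y0, y1, y2 = self.pdf[i - 1 : i + 2]
            denom = y0 - 2 * y1 + y2
            if denom != 0:
                shift = 0.5 * (y0 - y2) / denom
                return float(self.grid[i] + shift * (self.grid[1] - self.grid[0]))
        return float(self.grid[i])

    def mean(self) -> float:
        """Mean rupture force conditional on rupture within the ramp."""
        mass = np.trapezoid(self.pdf, self.grid)
        return float(np.trapezoid(self.grid * self.pdf, self.grid) / mass)

    def cdf(self, F) -> np.ndarray:
        """P(rupture force <= F), unconditional (saturates at 1 - survival)."""
        cum = np.concatenate(
            [[0.0], np.cumsum(0.5 * (self.pdf[1:] + self.pdf[:-1]) * np.diff(self.grid))]
        )
        return np.interp(np.asarray(F, dtype=float), self.grid, cum)

    def conditional_cdf(self, F) -> np.ndarray:
        """CDF conditioned on rupture occurring within the ramp."""
        return self.cdf(F) / (1.0 - self.survival)


def rupture_pdf(
    p: DsParams | DsMixture,
    schedule: LoadingSchedule,
    grid: np.ndarray | None = None,
    kBT: float = KBT_ROOM,
    rate_mode="effective",
    n_grid: int = 3001,
) -> RuptureDensity:
    """Rupture-force density p(F) = k/Fdot * S(F) under the schedule.

    Mixtures are weight-averaged.  By construction the density mass
    plus the terminal survival equals 1 (checked by the test suite via
    an independent time-domain Euler oracle).
    """
    mix = _as_mixture(p)
    f_lo = max(schedule.f_start, 0.0)
    if grid is None:
        grid = np.linspace(f_lo, schedule.f_max, n_grid)
    else:
        grid = np.asarray(grid, dtype=float)
        if grid.min() < 0 or grid.max() > schedule.f_max:
            raise ValueError("grid must lie within [0, F_max]")
    pdf = np.zeros_like(grid)
    surv_total = 0.0
    comp_surv = []
    comp_fc = []
    for comp, w in zip(mix.components, mix.weights):
        g, h, H = _hazard_grid(comp, schedule, kBT, rate_mode, n_grid)
        S = np.exp(-H)
        p_comp = h * S
        pdf += w * np.interp(grid, g, p_comp, left=0.0, right=0.0)
        comp_surv.append(float(S[-1]))
        comp_fc.append(comp.critical_force(kBT))
        surv_total += w * S[-1]
    return RuptureDensity(
        grid=grid,
        pdf=pdf,
        survival=float(surv_total),
        f_start=f_lo,
        f_max=float(schedule.f_max),
        component_survival=tuple(comp_surv),
        component_fc=tuple(comp_fc),
    )


def sample_ruptures(
    p: DsParams | DsMixture,
    schedule: LoadingSchedule,
    n: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    kBT: float = KBT_ROOM,
    rate_mode="effective",
    n_grid: int = 3001,
) -> RuptureSamples:
    """Draw ``n`` rupture forces by inverse-CDF of the cumulative hazard.

    Cycles surviving past the end of the usable ramp are returned as
    censored.  Reproducible given ``seed`` (or an explicit generator).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    mix = _as_mixture(p)
    comp_idx = rng.choice(len(mix.components), size=n, p=np.asarray(mix.weights))
    forces = np.full(n, np.nan)
    censored = np.zeros(n, dtype=bool)
    targets = -np.log(rng.random(n))
    for j, comp in enumerate(mix.components):
        sel = comp_idx == j
        if not sel.any():
            continue
        g, _, H = _hazard_grid(comp, schedule, kBT, rate_mode, n_grid)
        t = targets[sel]
        cen = t > H[-1]
        f = np.interp(t, H, g)
        forces[sel] = np.where(cen, np.nan, f)
        censored[sel] = cen
    keep = ~censored
    return RuptureSamples(
        forces=forces[keep],
        n_censored=int(censored.sum()),
        f_max=float(schedule.f_max),
        component_labels=comp_idx[keep],
    )


@dataclass
class DsFit:
    """Maximum-likelihood fit result."""

    mixture: DsMixture
    log_likelihood: float
    uncertainties: list[dict]
    n_uncensored: int
    n_censored: int
    converged: bool
    degenerate: bool = False


def _component_pdf_interp(
    comp: DsParams,
    forces: np.ndarray,
    schedule: LoadingSchedule,
    kBT: float,
    rate_mode,
    n_grid: int,
):
    """Per-sample density and terminal survival for one component."""
    g, h, H = _hazard_grid(comp, schedule, kBT, rate_mode, n_grid)
    S = np.exp(-H)
    p_obs = np.interp(forces, g, h * S, left=0.0, right=0.0)
    return p_obs, float(S[-1])


def fit_ds(
    samples: RuptureSamples,
    n_components: int = 1,
    schedule: LoadingSchedule | None = None,
    nu: float = 0.5,
    kBT: float = KBT_ROOM,
    n_starts: int = 20,
    seed: int = 0,
    rate_mode="effective",
    truncated: bool = False,
    n_grid: int = 1201,
) -> DsFit:
    """Censored maximum-likelihood fit of a Dudko-Szabo mixture.

    Fits (dx, tau0, dG) per component plus mixture weights to raw
    rupture forces; censored cycles contribute survival terms (or, with
    ``truncated=True``, the per-sample densities are renormalized by
    1 - S(F_max), for data known to contain only ruptured cycles).
    Multi-start Nelder-Mead from quantile-partitioned Bell-model
    initializations; parameter sets whose critical force falls below
    (max observed force)/0.95 are penalized, keeping the fit domain
    away from the vanishing-barrier pathology.  Uncertainties come from
    the observed information matrix (numerical Hessian in log space).
    """
    if schedule is None:
        raise ValueError("a LoadingSchedule is required")
    forces = np.sort(samples.forces)
    n_obs = len(forces)
    ncen = samples.n_censored
    if n_obs < 20 * n_components:
        raise InsufficientDataError(
            f"{n_obs} uncensored samples; need >= {20 * n_components} "
            f"for {n_components} component(s)"
        )
    if truncated and ncen:
        raise ValueError("truncated=True assumes no censored samples")
    fmax_obs = forces[-1]
    fc_floor = fmax_obs * (1.0 + 1e-6)
    rng = np.random.default_rng(seed)
    K = n_components
    eff_rate = (
        schedule.effective_rate
        if rate_mode == "effective"
        else float(np.mean(_rate_callable(schedule, rate_mode)(forces)))
    )

    def unpack(theta):
        comps = []
        for j in range(K):
            ldx, ltau, ldG = theta[3 * j : 3 * j + 3]
            comps.append(
                DsParams(
                    dx_dagger=float(np.exp(ldx)),
                    tau0=float(np.exp(ltau)),
                    dG_dagger=float(np.exp(ldG)),
                    nu=nu,
                )
            )
        if K == 1:
            w = np.ones(1)
        else:
            logits = np.concatenate([theta[3 * K :], [0.0]])
            w = np.exp(logits - logits.max())
            w /= w.sum()
        return comps, w

    def nll(theta):
        if np.any(np.abs(theta) > 30):
            return 1e9
        comps, w = unpack(theta)
        # at least one pathway must survive to the largest observed force;
        # weaker components are truncated at their own F_c and contribute
        # zero density beyond it (their samples are covered by the others)
        fcs = [comp.critical_force(kBT) for comp in comps]
        if max(fcs) <= fc_floor:
            return 1e6 + 1e4 * (1.0 + fc_floor - max(fcs))
        dens = np.zeros(n_obs)
        surv = 0.0
        for comp, wj, fc in zip(comps, w, fcs):
            if fc <= schedule.f_start * 1.05 + 1e-6:
                return 1e9
            try:
                p_obs, s_end = _component_pdf_interp(
                    comp, forces, schedule, kBT, rate_mode, n_grid
                )
            except (ValueError, OverflowError, FloatingPointError):
                return 1e9
            if truncated:
                denom = 1.0 - s_end
                if denom <= 1e-12:
                    return 1e9
                p_obs = p_obs / denom
                s_end = 0.0
            dens += wj * p_obs
            surv += wj * s_end
        val = -np.sum(np.log(np.maximum(dens, 1e-300)))
        if ncen:
            val -= ncen * np.log(max(surv, 1e-300))
        return val if np.isfinite(val) else 1e9

    def bell_init(block: np.ndarray) -> list[float]:
        """Bell-model moment guess (log dx, log tau0, log dG) for a cluster."""
        m = float(np.mean(block))
        s = max(float(np.std(block)), 0.2)
        dx0 = float(np.clip(kBT / s, 0.5, 15.0))
        tau0_0 = float(
            np.clip(kBT / (eff_rate * dx0) * np.exp(m * dx0 / kBT), 1e-3, 1e8)
        )
        dG0 = max(2.0 * fc_floor * nu * dx0 / kBT, 1.0)
        return [np.log(dx0), np.log(tau0_0), np.log(dG0)]

    # initialization: quantile-seeded 1-D k-means clusters, each polished
    # by a short single-component fit; the DS mixture likelihood has many
    # shallow local optima, so good starts matter more than extra iterations
    if K == 1:
        clusters = [forces]
    else:
        centers = np.quantile(forces, (2 * np.arange(K) + 1) / (2 * K))
        for _ in range(60):
            assign = np.argmin(np.abs(forces[:, None] - centers[None, :]), axis=1)
            new = np.array(
                [forces[assign == j].mean() if (assign == j).any() else centers[j] for j in range(K)]
            )
            if np.allclose(new, centers):
                break
            centers = new
        clusters = [forces[assign == j] for j in range(K)]

    theta0 = []
    w0 = []
    for j, blk in enumerate(clusters):
        init_j = bell_init(blk if len(blk) >= 5 else forces)
        if K > 1 and len(blk) >= 20:
            sub = RuptureSamples(
                forces=blk,
                n_censored=ncen if j == K - 1 else 0,
                f_max=samples.f_max,
            )
            try:
                subfit = fit_ds(
                    sub,
                    1,
                    schedule,
                    nu=nu,
                    kBT=kBT,
                    n_starts=3,
                    seed=seed + 1000 + j,
                    rate_mode=rate_mode,
                    n_grid=n_grid,
                )
                c = subfit.mixture.components[0]
                init_j = [np.log(c.dx_dagger), np.log(c.tau0), np.log(c.dG_dagger)]
            except (InsufficientDataError, ValueError):
                pass
        theta0 += init_j
        w0.append(max(len(blk), 1))
    w0 = np.asarray(w0, dtype=float) / np.sum(w0)
    theta0 = np.asarray(theta0)
    if K > 1:
        theta0 = np.concatenate([theta0, np.log(w0[:-1] / w0[-1])])

    nm_opts = {"maxiter": 600 * len(theta0), "xatol": 1e-5, "fatol": 1e-7}
    best = None
    for start in range(max(1, n_starts)):
        t_init = theta0.copy()
        if start > 0:
            t_init[: 3 * K] += rng.normal(0.0, 0.5, size=3 * K)
            if K > 1:
                t_init[3 * K :] += rng.normal(0.0, 0.5, size=K - 1)
        res = minimize(nll, t_init, method="Nelder-Mead", options=nm_opts)
        if best is None or res.fun < best.fun:
            best = res
    # polish: restart the simplex at the incumbent optimum
    res = minimize(nll, best.x, method="Nelder-Mead", options=nm_opts)
    if res.fun < best.fun:
        best = res
    degenerate = best.fun >= 1e6
    comps, w = unpack(best.x)
    w_orig = np.array(w, copy=True)

    # order components by modal force; ties broken by weight
    def comp_mode(comp):
        try:
            return rupture_pdf(comp, schedule, kBT=kBT, rate_mode=rate_mode, n_grid=801).mode()
        except ValueError:
            return np.inf

    order = sorted(range(K), key=lambda j: (comp_mode(comps[j]), -w[j]))
    comps = [comps[j] for j in order]
    w = np.array([w[j] for j in order])

    # observed-information uncertainties via central-difference Hessian;
    # the DS likelihood is notoriously flat along (dx, tau0, dG) trade-off
    # directions, so the pseudo-inverse keeps those variances honest (large)
    uncertainties: list[dict] = []
    x = best.x
    dim = len(x)
    try:
        step0 = 5e-3 * (1.0 + np.abs(x))
        Hm = np.empty((dim, dim))
        for a in range(dim):
            for b in range(a, dim):
                # shrink the step when a perturbation crosses the F_c
                # penalty boundary; a boundary-pinned direction gets zero
                # curvature and hence a large (honest) variance below
                val = 0.0
                for scale in (1.0, 0.2, 0.04):
                    ea = np.zeros(dim)
                    eb = np.zeros(dim)
                    ea[a] = step0[a] * scale
                    eb[b] = step0[b] * scale
                    evals = [
                        nll(x + ea + eb),
                        nll(x + ea - eb),
                        nll(x - ea + eb),
                        nll(x - ea - eb),
                    ]
                    if all(np.isfinite(v) and v < 1e5 for v in evals):
                        fpp, fpm, fmp, fmm = evals
                        val = (fpp - fpm - fmp + fmm) / (4 * ea[a] * eb[b])
                        break
                Hm[a, b] = Hm[b, a] = val
        # clamp flat / slightly negative curvature directions so their
        # variance stays finite but large rather than spuriously negative
        eigval, eigvec = np.linalg.eigh(Hm)
        floor = 1e-6 * max(float(eigval.max()), 1.0)
        cov = (eigvec / np.maximum(eigval, floor)) @ eigvec.T
        var = np.diag(cov)
        se_log = np.sqrt(np.maximum(var, 0.0))
        # weight SEs by the delta method through the softmax
        se_w = np.full(K, np.nan)
        if K > 1:
            jac = np.zeros((K, dim))
            for j in range(K):
                for b in range(K - 1):
                    jac[j, 3 * K + b] = w_orig[j] * ((1.0 if j == b else 0.0) - w_orig[b])
            var_w = np.einsum("ja,ab,jb->j", jac, cov, jac)
            se_w = np.sqrt(np.maximum(var_w, 0.0))
    except Exception:  # pragma: no cover - diagnostics only
        se_log = np.full(dim, np.nan)
        se_w = np.full(K, np.nan)
    for rank, j in enumerate(order):
        comp = comps[rank]
        uncertainties.append(
            {
                "dx_dagger_nm": comp.dx_dagger,
                "dx_dagger_se_nm": comp.dx_dagger * se_log[3 * j],
                "tau0_s": comp.tau0,
                "se_ln_tau0": se_log[3 * j + 1],
                "dG_dagger_kBT": comp.dG_dagger,
                "se_ln_dG_dagger": se_log[3 * j + 2],
                "weight": float(w[rank]),
                "weight_se": float(se_w[j]) if K > 1 else 0.0,
            }
        )
    return DsFit(
        mixture=DsMixture(components=tuple(comps), weights=tuple(float(v) for v in w)),
        log_likelihood=-float(best.fun),
        uncertainties=uncertainties,
        n_uncensored=n_obs,
        n_censored=ncen,
        converged=bool(best.success) and not degenerate,
        degenerate=degenerate,
    )


def reconstruct_profile(
    p: DsParams,
    schedule: LoadingSchedule,
    kBT: float = KBT_ROOM,
    rate_mode="effective",
    n_grid: int = 3001,
) -> dict:
    """Reconstruct k(F) and the predicted rupture-force profile.

    Returns the densely tabulated rate curve on [f_start, F_c), the
    predicted density under the schedule, the critical force and the
    modal and mean rupture forces.
    """
    dens = rupture_pdf(p, schedule, kBT=kBT, rate_mode=rate_mode, n_grid=n_grid)
    fc = p.critical_force(kBT)
    f_hi = min(schedule.f_max, fc * (1 - 1e-9))
    g = np.linspace(max(schedule.f_start, 0.0), f_hi, n_grid)
    return {
        "force_grid_pN": g,
        "rate_per_s": ds_rate(g, p, kBT),
        "density": dens,
        "critical_force_pN": fc,
        "modal_force_pN": dens.mode(),
        "mean_force_pN": dens.mean(),
        "survival_at_f_max": dens.survival,
    }
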