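"""No-U-Turn sampler (NUTS) with dual-averaging step-size adaptation.

A self-contained implementation of adaptive Hamiltonian Monte Carlo for a
differentiable unnormalized log density: the recursive tree-doubling NUTS
with slice sampling over the trajectory, a diagonal mass matrix estimated
from warmup draws in expanding windows, and Nesterov dual averaging of the
step size toward a target acceptance statistic. The interface is a single
function, :func:`sample_nuts`, taking a ``logp_and_grad`` callable.

Numerical conventions: a divergence is an energy error beyond 1000 nats;
trees stop doubling at ``max_treedepth`` (default 10); the estimated inverse
mass is regularized toward a small diagonal, as is standard.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["sample_nuts", "NutsResult"]

_DIVERGENCE_THRESHOLD = 1000.0


@dataclass
class NutsResult:
    samples: np.ndarray          # (n_kept, dim) post-warmup draws
    n_divergent: int             # divergent transitions after warmup
    n_divergent_warmup: int
    step_size: float
    inv_mass: np.ndarray         # diagonal of the inverse mass matrix
    mean_accept: float           # mean acceptance statistic after warmup
    tree_depths: np.ndarray = field(default=None)


class _DualAverage:
    """Nesterov dual averaging of log step size (Hoffman & Gelman 2014)."""

    def __init__(self, eps0: float, target: float, gamma: float = 0.05,
                 t0: float = 10.0, kappa: float = 0.75):
        self.mu = math.log(10.0 * eps0)
        self.target = target
        self.gamma = gamma
        self.t0 = t0
        self.kappa = kappa
        self.log_eps = math.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.count = 0

    def update(self, accept_stat: float) -> float:
        self.count += 1
        m = self.count
        eta = 1.0 / (m + self.t0)
        self.h_bar = (1 - eta) * self.h_bar + eta * (self.target - accept_stat)
        self.log_eps = self.mu - math.sqrt(m) / self.gamma * self.h_bar
        w = m ** (-self.kappa)
        self.log_eps_bar = w * self.log_eps + (1 - w) * self.log_eps_bar
        return math.exp(self.log_eps)

    @property
    def averaged(self) -> float:
        return math.exp(self.log_eps_bar)


class _Welford:
    """Streaming mean/variance for mass-matrix estimation."""

    def __init__(self, dim: int):
        self.n = 0
        self.mean = np.zeros(dim)
        self.m2 = np.zeros(dim)

    def add(self, x: np.ndarray) -> None:
        self.n += 1
        delta = x - self.mean
        self.mean += delta / self.n
        self.m2 += delta * (x - self.mean)

    def variance(self) -> np.ndarray:
        if self.n < 2:
            return np.ones_like(self.mean)
        return self.m2 / (self.n - 1)


def _adapt_schedule(n_warmup: int) -> tuple[int, list[int]]:
    """Return (end of initial fast phase, sorted iteration indices at which
    the mass matrix is re-estimated)."""
    if n_warmup < 20:
        return n_warmup, []
    init = max(1, int(round(0.15 * n_warmup)))
    term = max(1, int(round(0.10 * n_warmup)))
    middle = n_warmup - init - term
    if middle < 10:
        return n_warmup, []
    ends = []
    size = max(10, middle // 7)
    pos = init
    last = init + middle
    while pos < last:
        end = pos + size
        # if the next doubling could not fit, extend this window to the end
        if end + 2 * size > last:
            end = last
        ends.append(end)
        pos = end
        size *= 2
    return init, ends


def _find_reasonable_epsilon(logp_and_grad, q, inv_mass, rng) -> float:
    """Double/halve a trial step until the one-step acceptance crosses 1/2."""
    eps = 1.0
    logp, grad = logp_and_grad(q)
    p = rng.standard_normal(q.size) / np.sqrt(inv_mass)

    def joint(q_, p_):
        lp, _ = logp_and_grad(q_)
        return lp - 0.5 * np.sum(p_ * p_ * inv_mass), lp

    h0 = logp - 0.5 * np.sum(p * p * inv_mass)
    q1, p1, _, lp1 = _leapfrog(logp_and_grad, q, p, grad, eps, inv_mass)
    h1 = lp1 - 0.5 * np.sum(p1 * p1 * inv_mass)
    if not np.isfinite(h1):
        h1 = -np.inf
    direction = 1.0 if (h1 - h0) > math.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0 ** direction
        q1, p1, _, lp1 = _leapfrog(logp_and_grad, q, p, grad, eps, inv_mass)
        h1 = lp1 - 0.5 * np.sum(p1 * p1 * inv_mass)
        if not np.isfinite(h1):
            h1 = -np.inf
        if direction * (h1 - h0) <= direction * math.log(0.5):
            break
    return eps


def _leapfrog(logp_and_grad, q, p, grad, eps, inv_mass):
    p = p + 0.5 * eps * grad
    q = q + eps * inv_mass * p
    logp, grad = logp_and_grad(q)
    p = p + 0.5 * eps * grad
    return q, p, grad, logp


class _Tree:
    """Recursive NUTS trajectory builder (slice variant)."""

    __slots__ = ("f", "eps", "inv_mass", "logu", "h0", "rng",
                 "n_div", "sum_alpha", "n_alpha")

    def __init__(self, f, eps, inv_mass, logu, h0, rng):
        self.f = f
        self.eps = eps
        self.inv_mass = inv_mass
        self.logu = logu
        self.h0 = h0
        self.rng = rng
        self.n_div = 0
        self.sum_alpha = 0.0
        self.n_alpha = 0

    def _hamiltonian(self, logp, p):
        return logp - 0.5 * np.sum(p * p * self.inv_mass)

    def build(self, q, p, grad, direction, depth):
        """Returns (q-, p-, grad-, q+, p+, grad+, q_prop, n_prop, keep_going)."""
        if depth == 0:
            q1, p1, grad1, logp1 = _leapfrog(
                self.f, q, p, grad, direction * self.eps, self.inv_mass
            )
            h1 = self._hamiltonian(logp1, p1)
            if not np.isfinite(h1):
                h1 = -np.inf
            n_prop = 1 if self.logu <= h1 else 0
            diverged = (self.logu - _DIVERGENCE_THRESHOLD) >= h1
            if diverged:
                self.n_div += 1
            self.sum_alpha += min(1.0, math.exp(min(0.0, h1 - self.h0)))
            self.n_alpha += 1
            return q1, p1, grad1, q1, p1, grad1, q1, n_prop, not diverged
        # inner subtree
        qm, pm, gm, qp, pp, gp, q_prop, n_prop, ok = self.build(
            q, p, grad, direction, depth - 1
        )
        if ok:
            if direction == -1:
                qm, pm, gm, _, _, _, q_prop2, n2, ok2 = self.build(
                    qm, pm, gm, direction, depth - 1
                )
            else:
                _, _, _, qp, pp, gp, q_prop2, n2, ok2 = self.build(
                    qp, pp, gp, direction, depth - 1
                )
            total = n_prop + n2
            if n2 > 0 and self.rng.random() < n2 / total:
                q_prop = q_prop2
            n_prop = total
            ok = ok2 and self._no_uturn(qm, pm, qp, pp)
        return qm, pm, gm, qp, pp, gp, q_prop, n_prop, ok

    def _no_uturn(self, qm, pm, qp, pp):
        dq = qp - qm
        return (np.dot(dq, self.inv_mass * pm) >= 0) and (
            np.dot(dq, self.inv_mass * pp) >= 0
        )


def sample_nuts(
    logp_and_grad,
    q0: np.ndarray,
    *,
    n_iterations: int,
    n_warmup: int,
    rng: np.random.Generator,
    target_accept: float = 0.9,
    max_treedepth: int = 10,
    inv_mass0: np.ndarray | None = None,
) -> NutsResult:
    """Draw from a log density with NUTS; returns post-warmup samples.

    ``logp_and_grad(q) -> (float, ndarray)`` must be finite at ``q0``.
    ``n_iterations`` counts all transitions including the ``n_warmup``
    adaptation iterations that are discarded.
    """
    q = np.asarray(q0, dtype=float).copy()
    dim = q.size
    logp, grad = logp_and_grad(q)
    if not np.isfinite(logp):
        raise ValueError("initial point has non-finite log density")

    if inv_mass0 is None:
        inv_mass0_arr = np.ones(dim)
    else:
        inv_mass0_arr = np.asarray(inv_mass0, dtype=float).copy()
        if inv_mass0_arr.shape != (dim,) or np.any(inv_mass0_arr <= 0):
            raise ValueError("inv_mass0 must be a positive vector of length dim")
    inv_mass = inv_mass0_arr.copy()
    eps = _find_reasonable_epsilon(logp_and_grad, q, inv_mass, rng)
    da = _DualAverage(eps, target_accept)
    fast_end, window_ends = _adapt_schedule(n_warmup)
    welford = _Welford(dim)

    n_kept = n_iterations - n_warmup
    samples = np.empty((n_kept, dim))
    depths = np.empty(n_iterations, dtype=np.int16)
    n_div_warm = 0
    n_div = 0
    accept_sum = 0.0

    for it in range(n_iterations):
        p0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        h0 = logp - 0.5 * np.sum(p0 * p0 * inv_mass)
        logu = h0 - rng.exponential()
        tree = _Tree(logp_and_grad, eps, inv_mass, logu, h0, rng)
        qm = qp = q
        pm = pp = p0
        gm = gp = grad
        n_total = 1
        depth = 0
        keep_going = True
        while keep_going and depth < max_treedepth:
            direction = 1 if rng.random() < 0.5 else -1
            if direction == -1:
                qm, pm, gm, _, _, _, q_prop, n_prop, ok = tree.build(
                    qm, pm, gm, -1, depth
                )
            else:
                _, _, _, qp, pp, gp, q_prop, n_prop, ok = tree.build(
                    qp, pp, gp, 1, depth
                )
            if ok and n_prop > 0 and rng.random() < min(1.0, n_prop / n_total):
                q = q_prop
            n_total += n_prop
            keep_going = ok and tree._no_uturn(qm, pm, qp, pp)
            depth += 1
        logp, grad = logp_and_grad(q)
        depths[it] = depth
        alpha = tree.sum_alpha / max(tree.n_alpha, 1)

        if it < n_warmup:
            n_div_warm += tree.n_div
            eps = da.update(alpha)
            if fast_end <= it and window_ends and it < window_ends[-1]:
                welford.add(q)
            if window_ends and (it + 1) in window_ends:
                var = welford.variance()
                n = welford.n
                # shrink the noisy window estimate toward the starting metric
                # (curvature-based when the caller supplied one), not toward a
                # fixed diagonal: coordinate scales here span orders of
                # magnitude
                shrink = inv_mass0_arr
                inv_mass = (n / (n + 5.0)) * var + shrink * (5.0 / (n + 5.0))
                inv_mass = np.maximum(inv_mass, 1e-10)
                welford = _Welford(dim)
                da = _DualAverage(max(da.averaged, 1e-10), target_accept)
                eps = math.exp(da.log_eps)
            if it == n_warmup - 1:
                eps = da.averaged
        else:
            n_div += tree.n_div
            accept_sum += alpha
            samples[it - n_warmup] = q

    return NutsResult(
        samples=samples,
        n_divergent=n_div,
        n_divergent_warmup=n_div_warm,
        step_size=eps,
        inv_mass=inv_mass,
        mean_accept=accept_sum / max(n_kept, 1),
        tree_depths=depths,
    )
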