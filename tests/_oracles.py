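"""Independent oracle implementations used to cross-check the package.

Everything here is deliberately written from scratch against the model
definition, using scipy.stats densities and naive loops, and must not import
computational code paths from :mod:`wingallometry` beyond plain containers.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def mad_keep_mask_bruteforce(values, k=5.0):
    """Brute-force 5-MAD screen: sorted-copy medians, elementwise loop."""
    values = list(float(v) for v in values)
    med = float(np.sort(values)[len(values) // 2]) if len(values) % 2 == 1 else \
        float(np.mean(np.sort(values)[len(values) // 2 - 1:len(values) // 2 + 1]))
    devs = sorted(abs(v - med) for v in values)
    mad = devs[len(devs) // 2] if len(devs) % 2 == 1 else \
        float(np.mean(devs[len(devs) // 2 - 1:len(devs) // 2 + 1]))
    return [abs(v - med) <= k * mad for v in values]


def pd_bruteforce(samples):
    """Counting definition of the probability of direction."""
    pos = sum(1 for x in samples if x > 0)
    neg = sum(1 for x in samples if x < 0)
    n = len(samples)
    pd_pct = 100.0 * max(pos, neg) / n
    if pos > neg:
        direction = "+"
    elif neg > pos:
        direction = "-"
    else:
        direction = "tie"
    return pd_pct, direction


def log_joint_oracle(params, data, G, normal_scale=2.0, cauchy_scale=5.0):
    """Observation-by-observation sum of scipy.stats log densities.

    ``params`` is a ModelParameters-like object; ``data`` an iterable of
    (species, year, sex_code, z, w) rows; ``G`` maps (species, year) to a
    design vector.
    """
    sp_index = {s: i for i, s in enumerate(params.species)}
    cell_index = {c: i for i, c in enumerate(params.cells)}

    all_scales = list(np.atleast_1d(params.sigma0)) + \
        list(np.atleast_1d(params.sigma1)) + \
        [params.tau0, params.tau1, params.sigma_w, params.s_n0, params.s_n1]
    if any(s <= 0 for s in all_scales):
        return -np.inf

    total = 0.0
    for (species, year, sex, z, w) in data:
        jj = cell_index[(species, int(year))]
        pp = sp_index[species]
        mean = (params.beta0[jj] + params.beta1[jj] * z
                + params.n0[pp] * sex + params.n1[pp] * sex * z)
        total += stats.norm.logpdf(w, mean, params.sigma_w)
    for jj, (species, year) in enumerate(params.cells):
        pp = sp_index[species]
        g = np.asarray(G[(species, year)], dtype=float)
        total += stats.norm.logpdf(
            params.beta0[jj], float(np.sum(params.I0[pp] * g)), params.tau0)
        total += stats.norm.logpdf(
            params.beta1[jj], float(np.sum(params.I1[pp] * g)), params.tau1)
    for pp in range(len(params.species)):
        total += stats.norm.logpdf(params.n0[pp], params.m_n0, params.s_n0)
        total += stats.norm.logpdf(params.n1[pp], params.m_n1, params.s_n1)
        for c in range(len(params.columns)):
            total += stats.norm.logpdf(
                params.I0[pp, c], params.mu0[c], params.sigma0[c])
            total += stats.norm.logpdf(
                params.I1[pp, c], params.mu1[c], params.sigma1[c])
    for c in range(len(params.columns)):
        total += stats.norm.logpdf(params.mu0[c], 0.0, normal_scale)
        total += stats.norm.logpdf(params.mu1[c], 0.0, normal_scale)
        total += stats.halfcauchy.logpdf(params.sigma0[c], scale=cauchy_scale)
        total += stats.halfcauchy.logpdf(params.sigma1[c], scale=cauchy_scale)
    total += stats.norm.logpdf(params.m_n0, 0.0, normal_scale)
    total += stats.norm.logpdf(params.m_n1, 0.0, normal_scale)
    for s in (params.tau0, params.tau1, params.sigma_w,
              params.s_n0, params.s_n1):
        total += stats.halfcauchy.logpdf(s, scale=cauchy_scale)
    return float(total)


def random_model_instance(rng, max_species=3, max_years=4, max_obs=10):
    """A random tiny model instance: (params, data_rows, G_dict, data_frame)."""
    from wingallometry.model import ModelParameters

    S = int(rng.integers(1, max_species + 1))
    n_years = int(rng.integers(1, max_years + 1))
    C = int(rng.integers(1, 4))
    species = [f"s{i}" for i in range(S)]
    years = list(range(2000, 2000 + n_years))
    cells = [(sp, y) for sp in species for y in years]
    columns = [f"c{i}" for i in range(C)]

    G = {}
    for cell in cells:
        g = rng.normal(size=C)
        g[0] = 1.0
        G[cell] = g
    params = ModelParameters(
        cells=cells, species=species, columns=columns,
        beta0=rng.normal(size=len(cells)), beta1=rng.normal(size=len(cells)),
        n0=rng.normal(size=S), n1=rng.normal(size=S),
        I0=rng.normal(size=(S, C)), I1=rng.normal(size=(S, C)),
        mu0=rng.normal(size=C), mu1=rng.normal(size=C),
        sigma0=np.abs(rng.normal(size=C)) + 0.1,
        sigma1=np.abs(rng.normal(size=C)) + 0.1,
        tau0=float(np.abs(rng.normal())) + 0.1,
        tau1=float(np.abs(rng.normal())) + 0.1,
        sigma_w=float(np.abs(rng.normal())) + 0.1,
        m_n0=float(rng.normal()), m_n1=float(rng.normal()),
        s_n0=float(np.abs(rng.normal())) + 0.1,
        s_n1=float(np.abs(rng.normal())) + 0.1,
    )
    n_obs = int(rng.integers(1, max_obs + 1))
    rows = []
    for _ in range(n_obs):
        sp, y = cells[int(rng.integers(len(cells)))]
        rows.append((sp, y, int(rng.integers(2)),
                     float(rng.normal()), float(rng.normal())))
    return params, rows, G
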