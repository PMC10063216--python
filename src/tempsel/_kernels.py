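"""Compiled inner loops: Euler-Maruyama propagation and the bootstrap particle filter.

These are the hot paths of the pseudo-marginal sampler, so they are written as
scalar loops and compiled with numba. The kernels draw no randomness of their
own: all normals and uniforms are pre-drawn by the caller from an explicit
:class:`numpy.random.Generator`, so a single integer seed reproduces any run
exactly and the vectorized bit generator keeps sampling cheap.
"""

import numpy as np
from numba import njit


@njit(inline="always")
def _geno_probs(x, s, h):
    # Hardy-Weinberg genotype proportions reweighted by viabilities 1, 1+hs, 1+s.
    if x <= 0.0:
        return 1.0, 0.0, 0.0
    if x >= 1.0:
        return 0.0, 0.0, 1.0
    a = (1.0 - x) * (1.0 - x)
    b = 2.0 * (1.0 + h * s) * x * (1.0 - x)
    c = (1.0 + s) * x * x
    w = a + b + c
    return a / w, b / w, c / w


@njit(inline="always", fastmath=True)
def _euler_step(x, s, h, beta, n0, dt, z):
    # Boundaries are absorbing: drift and noise both vanish at 0 and 1.
    if x <= 0.0:
        return 0.0
    if x >= 1.0:
        return 1.0
    v = x * (1.0 - x)
    drift = 2.0 * n0 * s * v * (h + (1.0 - 2.0 * h) * x) * dt
    y = x + drift + np.sqrt(v / beta * dt) * z
    if y < 0.0:
        y = 0.0
    elif y > 1.0:
        y = 1.0
    return y


@njit(inline="always", fastmath=True)
def _euler_step_v(x, s, h, vdt, n0, dt, z):
    # identical to _euler_step with dt/beta pre-divided into vdt
    if x <= 0.0:
        return 0.0
    if x >= 1.0:
        return 1.0
    v = x * (1.0 - x)
    drift = 2.0 * n0 * s * v * (h + (1.0 - 2.0 * h) * x) * dt
    y = x + drift + np.sqrt(v * vdt) * z
    if y < 0.0:
        y = 0.0
    elif y > 1.0:
        y = 1.0
    return y


@njit(cache=False)
def _euler_paths(x0, gen_from, gen_to, substeps, s_by_gen, beta_by_gen, h, n0, normals):
    """Propagate a batch of frequencies from gen_from to gen_to.

    x0: (B,) start frequencies; normals: (B, (gen_to-gen_from)*substeps)
    pre-drawn standard normals. s and beta are evaluated at the left endpoint
    of each generation (piecewise-constant in generations).
    """
    B = x0.shape[0]
    out = np.empty(B)
    dt = 1.0 / (2.0 * n0 * substeps)
    for b in range(B):
        x = x0[b]
        j = 0
        for g in range(gen_from, gen_to):
            s = s_by_gen[g]
            beta = beta_by_gen[g]
            for _ in range(substeps):
                x = _euler_step(x, s, h, beta, n0, dt, normals[b, j])
                j += 1
        out[b] = x
    return out


@njit(cache=False)
def _bpf(M, gl, offsets, sample_gens, s_by_gen, beta_by_gen, h, n0,
         substeps, x1_lo, x1_hi, systematic, u_init, normals, u_res, u_final):
    """Bootstrap particle filter over the sampling time grid.

    All randomness is supplied pre-drawn by the caller: u_init (M,) uniforms
    for the starting-frequency prior, normals (M, total substeps across the
    sampling span) for the Euler-Maruyama increments, u_res (K, M) uniforms
    for resampling, and u_final for the smoothing draw.

    Returns (log_marginal, smoothing path of one uniformly drawn final
    particle traced through its ancestry, per-time effective sample size).
    If every particle has zero emission weight at some time point, returns
    (-inf, nan path, ess so far).
    """
    K = sample_gens.shape[0]
    dt = 1.0 / (2.0 * n0 * substeps)
    dtb = dt / beta_by_gen  # noise variance factor per generation
    x = np.empty(M)
    for m in range(M):
        x[m] = x1_lo + (x1_hi - x1_lo) * u_init[m]
    paths = np.zeros((M, K))
    logw = np.empty(M)
    probs = np.empty(M)
    ess = np.zeros(K)
    log_marg = 0.0
    j0 = 0
    for k in range(K):
        if k > 0:
            for m in range(M):
                xm = x[m]
                j = j0
                for g in range(sample_gens[k - 1], sample_gens[k]):
                    s = s_by_gen[g]
                    vdt = dtb[g]
                    for _ in range(substeps):
                        xm = _euler_step_v(xm, s, h, vdt, n0, dt, normals[m, j])
                        j += 1
                x[m] = xm
            j0 = j0 + (sample_gens[k] - sample_gens[k - 1]) * substeps
        for m in range(M):
            paths[m, k] = x[m]
        sk = s_by_gen[sample_gens[k]]
        for m in range(M):
            p0, p1, p2 = _geno_probs(x[m], sk, h)
            ll = 0.0
            for n in range(offsets[k], offsets[k + 1]):
                w = gl[n, 0] * p0 + gl[n, 1] * p1 + gl[n, 2] * p2
                if w <= 0.0:
                    ll = -np.inf
                    break
                ll += np.log(w)
            logw[m] = ll
        mx = -np.inf
        for m in range(M):
            if logw[m] > mx:
                mx = logw[m]
        if mx == -np.inf:
            return -np.inf, np.full(K, np.nan), ess
        tot = 0.0
        for m in range(M):
            probs[m] = np.exp(logw[m] - mx)
            tot += probs[m]
        # marginal-likelihood factor from pre-resampling weights (log-sum-exp)
        log_marg += mx + np.log(tot) - np.log(M)
        sq = 0.0
        for m in range(M):
            probs[m] /= tot
            sq += probs[m] * probs[m]
        ess[k] = 1.0 / sq
        c = np.empty(M)
        acc = 0.0
        for m in range(M):
            acc += probs[m]
            c[m] = acc
        c[M - 1] = 1.0
        newx = np.empty(M)
        newpaths = np.empty((M, K))
        if systematic:
            i = 0
            u0 = u_res[k, 0] / M
            for m in range(M):
                u = u0 + m / M
                while c[i] < u:
                    i += 1
                newx[m] = x[i]
                for kk in range(k + 1):
                    newpaths[m, kk] = paths[i, kk]
        else:
            for m in range(M):
                i = np.searchsorted(c, u_res[k, m])
                if i >= M:
                    i = M - 1
                newx[m] = x[i]
                for kk in range(k + 1):
                    newpaths[m, kk] = paths[i, kk]
        x = newx
        paths = newpaths
    j = int(u_final * M)
    if j >= M:
        j = M - 1
    out_path = np.empty(K)
    for kk in range(K):
        out_path[kk] = paths[j, kk]
    return log_marg, out_path, ess


@njit(inline="always")
def _post_sel(x, s, h):
    # deterministic selection update (same closed form as core.post_selection_freq)
    if x <= 0.0:
        return 0.0
    if x >= 1.0:
        return 1.0
    wbar = (1.0 - x) ** 2 + 2.0 * x * (1.0 - x) * (1.0 + h * s) + x * x * (1.0 + s)
    return (x * x * (1.0 + s) + x * (1.0 - x) * (1.0 + h * s)) / wbar


@njit(cache=False)
def _wf_discrete(seed, x1, n_gen, s_by_gen, sizes_by_gen, h):
    """Discrete Wright-Fisher trajectory: binomial resampling of 2N(k+1)
    gametes at the post-selection frequency; absorbing boundaries.

    Uses numba's np.random state seeded per call (binomial draws cannot be
    pre-drawn since their parameters depend on the running state).
    """
    np.random.seed(seed)
    freqs = np.empty(n_gen)
    freqs[0] = x1
    x = x1
    for k in range(n_gen - 1):
        if x <= 0.0 or x >= 1.0:
            for j in range(k + 1, n_gen):
                freqs[j] = x
            return freqs
        p = _post_sel(x, s_by_gen[k], h)
        n2 = 2 * sizes_by_gen[k + 1]
        x = np.random.binomial(n2, p) / n2
        freqs[k + 1] = x
    return freqs
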