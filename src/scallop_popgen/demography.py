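"""Composite-likelihood demographic inference from the folded joint SFS.

The observed spectrum is treated as a multinomial sample over polymorphic
folded entries; entry probabilities under a candidate parameter vector are
estimated by Monte-Carlo coalescent simulation and the composite
log-likelihood ``lnCL = sum_e m_e ln p_e`` is maximized by repeated cycles
of Nelder-Mead search in log10-parameter space.  Within a cycle all
candidate evaluations share one simulation seed (common random numbers), so
the optimizer sees a fixed noisy surface; the seed is refreshed between
cycles.  Models are compared with the composite-likelihood AIC
``2k - 2 lnCL`` and parameter uncertainty comes from a parametric
bootstrap.

Because SNP simulation is conditioned on polymorphism (no mutation rate),
the expected SFS is invariant to a joint rescaling of all sizes and times;
absolute times in generations are identified only once a reference size
anchors the scale, so fits intended to report times in generations should
fix one size parameter via ``ModelSpec.fixed``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .coalescent import expected_folded_sfs, sample_snp_counts
from .models import ModelSpec
from .sfs import FoldedJointSFS, fold_configurations

__all__ = [
    "FitResult", "compute_folded_joint_sfs", "select_complete_subset",
    "composite_loglik", "simulate_observed_sfs", "fit_model", "model_aic",
    "select_model", "parametric_bootstrap",
]


# ---------------------------------------------------------------------------
# observed SFS construction
# ---------------------------------------------------------------------------


def compute_folded_joint_sfs(calls, deme_of_individual: dict[str, str],
                             subset: list[str] | None = None) -> FoldedJointSFS:
    """Folded joint SFS from a genotype call set.

    ``deme_of_individual`` maps individual id -> deme name; ``subset``
    optionally restricts to a list of individual ids.  Loci with any
    missing genotype among the subset are dropped (the spectrum admits no
    missing data), each remaining SNP increments its folded configuration.
    """
    ids = list(calls.individuals)
    if subset is None:
        subset = [i for i in ids if i in deme_of_individual]
    if not subset:
        raise ValueError("empty individual subset")
    idx = [ids.index(s) for s in subset]
    demes = sorted({deme_of_individual[s] for s in subset})
    geno = calls.genotypes[idx]
    complete = ~(geno < 0).any(axis=0)
    geno = geno[:, complete]
    if geno.shape[1] == 0:
        raise ValueError("no loci with complete genotypes in the subset")
    deme_idx = np.array([demes.index(deme_of_individual[s]) for s in subset])
    sizes = np.array([2 * (deme_idx == d).sum() for d in range(len(demes))],
                     dtype=np.int64)
    counts = np.zeros((geno.shape[1], len(demes)), dtype=np.int64)
    for d in range(len(demes)):
        counts[:, d] = geno[deme_idx == d].sum(axis=0)
    return FoldedJointSFS.from_count_matrix(counts, demes, sizes)


def select_complete_subset(calls, deme_of_individual: dict[str, str],
                           n_per_deme: dict[str, int]) -> list[str]:
    """Pick individuals per deme with the fewest missing calls.

    Greedy heuristic for the complete-case subset used in SFS estimation:
    within each deme, individuals are ranked by their missing-call count and
    the least-missing ``n_per_deme[deme]`` are retained.
    """
    missing = (calls.genotypes < 0).sum(axis=1)
    chosen: list[str] = []
    ids = np.asarray(calls.individuals)
    for deme, n in n_per_deme.items():
        members = [i for i, s in enumerate(ids) if deme_of_individual.get(s) == deme]
        if len(members) < n:
            raise ValueError(f"deme {deme}: requested {n} individuals, "
                             f"only {len(members)} available")
        order = sorted(members, key=lambda i: (missing[i], i))
        chosen.extend(ids[i] for i in order[:n])
    return chosen


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------


def composite_loglik(obs: FoldedJointSFS, expected_probs: np.ndarray,
                     p_min: float = 1e-8, pool_min: int = 0) -> tuple[float, int]:
    """``sum_e m_e ln p_e`` over polymorphic folded entries (natural log).

    Entries observed but assigned zero probability by the Monte-Carlo
    estimate are floored at ``p_min``; the number of floored entries is
    returned alongside the value.

    With ``pool_min > 0``, entries observed fewer than ``pool_min`` times
    are aggregated into a single class (their counts summed, their
    probabilities summed) before the log-likelihood is taken.  Pooling
    sparse entries drastically reduces the Monte-Carlo noise of the
    estimate at a modest cost in information, exactly as SFS likelihood
    implementations pool rarely observed entries.
    """
    m = obs.counts.reshape(-1)
    p = np.asarray(expected_probs, dtype=float).reshape(-1)
    if m.shape != p.shape:
        raise ValueError("observed SFS and expected probabilities differ in shape")
    if (m < 0).any():
        raise ValueError("negative observed counts")
    if pool_min > 0:
        keep = m >= pool_min
        m_pool = int(m[~keep].sum())
        p_pool = float(p[~keep].sum())
        mk = m[keep]
        pk = p[keep]
        floored = int((pk < p_min).sum())
        lnl = float(mk @ np.log(np.maximum(pk, p_min)))
        if m_pool > 0:
            floored += p_pool < p_min
            lnl += m_pool * np.log(max(p_pool, p_min))
        return lnl, floored
    nz = m > 0
    floored = int((p[nz] < p_min).sum())
    lnp = np.log(np.maximum(p[nz], p_min))
    return float(m[nz] @ lnp), floored


def simulate_observed_sfs(model: ModelSpec, params: dict[str, float],
                          n_snps: int, rng_seed: int) -> FoldedJointSFS:
    """Draw an observed folded SFS of ``n_snps`` SNPs under the model."""
    demes, events = model.demography(params)
    counts = sample_snp_counts(demes, events, n_snps, rng_seed)
    names = [d.deme_id for d in demes]
    sizes = np.array([d.sample_size for d in demes], dtype=np.int64)
    keep = sizes > 0
    return FoldedJointSFS.from_count_matrix(
        counts[:, keep], [n for n, k in zip(names, keep) if k], sizes[keep])


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    model_id: str
    params: dict[str, float]
    max_loglik: float
    k: int
    aic: float
    n_runs: int
    trace: list[dict] = field(default_factory=list)
    n_floored: int = 0

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "params": self.params,
            "max_loglik": self.max_loglik,
            "k": self.k,
            "aic": self.aic,
            "n_runs": self.n_runs,
        }


def _objective_factory(obs: FoldedJointSFS, model: ModelSpec, n_sims: int,
                       lo: np.ndarray, hi: np.ndarray, free: tuple[str, ...],
                       p_min: float, pool_min: int = 0):
    def objective(x_log10: np.ndarray, sim_seed: int) -> float:
        # soft penalty outside the (log-space) box keeps Nelder-Mead informed
        over = np.maximum(0.0, x_log10 - hi) + np.maximum(0.0, lo - x_log10)
        if over.sum() > 0:
            return 1e8 * (1.0 + over.sum())
        params = model.full_params(dict(zip(free, 10.0 ** np.asarray(x_log10))))
        if not model.valid(params):
            viol = 0.0
            if params["t_dmj"] <= params["t_div"]:
                viol += np.log10(params["t_div"] / params["t_dmj"]) + 0.01
            if "t_exp" in model.param_names:
                if params["t_exp"] >= params["t_dmj"]:
                    viol += np.log10(params["t_exp"] / params["t_dmj"]) + 0.01
                if params["t_exp"] <= params["t_div"]:
                    viol += np.log10(params["t_div"] / params["t_exp"]) + 0.01
            for deme in ("ATL", "NOR", "JAC"):
                cur, hist = params[f"Ne_cur_{deme}"], params[f"Ne_hist_{deme}"]
                if cur <= hist:
                    viol += np.log10(hist / cur) + 0.01
            return 1e8 * (1.0 + viol)
        demes, events = model.demography(params)
        probs = expected_folded_sfs(demes, events, n_sims, sim_seed)
        lnl, _ = composite_loglik(obs, probs, p_min, pool_min)
        return -lnl

    def objective_multi(x_log10: np.ndarray, sim_seeds) -> float:
        # averaging probabilities before the log removes most of the
        # Jensen bias of E[ln p-hat], which otherwise penalizes parameter
        # regions with higher Monte-Carlo variance
        over = np.maximum(0.0, x_log10 - hi) + np.maximum(0.0, lo - x_log10)
        if over.sum() > 0:
            return objective(x_log10, int(sim_seeds[0]))
        params = model.full_params(dict(zip(free, 10.0 ** np.asarray(x_log10))))
        if not model.valid(params):
            return objective(x_log10, int(sim_seeds[0]))
        demes, events = model.demography(params)
        probs = np.mean([expected_folded_sfs(demes, events, n_sims, int(s2))
                         for s2 in sim_seeds], axis=0)
        lnl, _ = composite_loglik(obs, probs, p_min, pool_min)
        return -lnl

    return objective, objective_multi


def _draw_start(rng: np.random.Generator, model: ModelSpec,
                lo: np.ndarray, hi: np.ndarray, free) -> np.ndarray:
    for _ in range(1000):
        x = rng.uniform(lo, hi)
        params = model.full_params(dict(zip(free, 10.0 ** x)))
        if model.valid(params):
            return x
    raise RuntimeError("could not draw a valid start from the prior box")


def fit_model(obs: FoldedJointSFS, model: ModelSpec, n_runs: int = 50,
              n_sims: int = 100_000, n_cycles: int = 40, rng_seed: int = 0,
              evals_per_cycle: int = 12, start_pool: int = 16,
              polish_evals: int = 60, polish_avg: int = 8,
              p_min: float = 1e-8, pool_min: int = 5,
              extra_starts: list[dict] | None = None,
              final_avg: int = 4) -> FitResult:
    """Maximize the composite likelihood by multi-start Nelder-Mead.

    Each run is one continuous adaptive Nelder-Mead search in
    log10-parameter space with an evaluation budget of ``n_cycles x
    evals_per_cycle``; the Monte-Carlo simulation seed is refreshed at
    every cycle boundary (common random numbers within a cycle), so the
    optimizer sees a fixed noisy surface that is re-drawn ``n_cycles``
    times as it converges.  Run starts are log-uniform prior draws: each
    run draws ``start_pool`` candidate points, scores them once under a
    shared seed and starts from the best.  Runs are compared on a common
    final evaluation seed; the winner gets a short polish pass whose
    objective averages ``polish_avg`` simulation seeds per evaluation
    (quadrupling the effective simulation count to damp Monte-Carlo noise
    near the optimum).
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    free = model.free_names
    lo = np.log10([model.bounds[n][0] for n in free])
    hi = np.log10([model.bounds[n][1] for n in free])
    objective, objective_multi = _objective_factory(obs, model, n_sims, lo,
                                                    hi, free, p_min, pool_min)
    ss = np.random.SeedSequence([int(rng_seed) & 0x7FFFFFFF, 0xD3])
    run_seeds = ss.spawn(n_runs)
    eval_seeds = [int(v >> 1) for v in ss.generate_state(max(1, final_avg))]

    def final_eval(xv):
        # runs and models are compared on this common low-noise,
        # probability-averaged evaluation
        return objective_multi(xv, eval_seeds)

    best_overall: tuple[float, np.ndarray] | None = None
    trace = []
    for r, rs in enumerate(run_seeds):
        rng = np.random.default_rng(rs)
        cycle_seeds = rng.integers(0, 2**31, size=n_cycles)
        starts = [_draw_start(rng, model, lo, hi, free)
                  for _ in range(max(1, start_pool))]
        if extra_starts and r < len(extra_starts):
            cand = np.log10([max(model.bounds[n][0],
                                 min(model.bounds[n][1], extra_starts[r][n]))
                             for n in free])
            params = model.full_params(dict(zip(free, 10.0 ** cand)))
            if model.valid(params):
                starts.append(cand)
        x = min(starts, key=lambda s: objective(s, int(cycle_seeds[0])))
        counter = {"n": 0}

        def blocked(xv):
            c = min(counter["n"] // evals_per_cycle, n_cycles - 1)
            counter["n"] += 1
            return objective(xv, int(cycle_seeds[c]))

        simplex = np.vstack([x] + [np.clip(x + 0.3 * basis, lo, hi)
                                   for basis in np.eye(len(free))])
        res = minimize(blocked, x, method="Nelder-Mead",
                       options={"maxfev": n_cycles * evals_per_cycle,
                                "maxiter": n_cycles * evals_per_cycle,
                                "initial_simplex": simplex, "adaptive": True,
                                "xatol": 1e-5, "fatol": 1e-4})
        x = res.x
        final = final_eval(x)
        trace.append({"run": r, "loglik": -final,
                      "params": dict(zip(free, 10.0 ** x))})
        if best_overall is None or final < best_overall[0]:
            best_overall = (final, x.copy())
    assert best_overall is not None
    neg, x = best_overall
    if polish_evals > 0:
        polish_seeds = [int(s) for s in
                        np.random.SeedSequence([int(rng_seed) & 0x7FFFFFFF,
                                                0x90]).generate_state(polish_avg) >> np.uint32(1)]

        def averaged(xv):
            return objective_multi(xv, polish_seeds)

        simplex = np.vstack([x] + [np.clip(x + 0.05 * basis, lo, hi)
                                   for basis in np.eye(len(free))])
        res = minimize(averaged, x, method="Nelder-Mead",
                       options={"maxfev": polish_evals, "adaptive": True,
                                "initial_simplex": simplex,
                                "xatol": 1e-5, "fatol": 1e-4})
        if final_eval(res.x) <= final_eval(x):
            x = res.x
    params = model.full_params(dict(zip(free, 10.0 ** x)))
    lnl = -final_eval(x)
    # floored-entry count at the optimum, for reporting
    demes, events = model.demography(params)
    probs = expected_folded_sfs(demes, events, n_sims, eval_seeds[0])
    _, n_floored = composite_loglik(obs, probs, p_min, pool_min)
    k = model.k
    return FitResult(model.model_id, params, lnl, k, 2 * k - 2 * lnl,
                     n_runs, trace, n_floored)


def model_aic(fit: FitResult) -> float:
    """Composite-likelihood AIC, ``2k - 2 max lnCL`` (natural-log scale)."""
    return 2 * fit.k - 2 * fit.max_loglik


def select_model(fits: list[FitResult]) -> list[FitResult]:
    """Rank fits by ascending AIC (best model first)."""
    if not fits:
        raise ValueError("no fits to rank")
    return sorted(fits, key=lambda f: f.aic)


def parametric_bootstrap(best_fit: FitResult, model: ModelSpec, n_snps: int,
                         n_boot: int = 100, rng_seed: int = 0,
                         fit_kwargs: dict | None = None,
                         ci_method: str = "percentile"):
    """95% CIs by simulate-and-refit at the fitted parameters.

    Each replicate draws an observed SFS of ``n_snps`` SNPs at the fitted
    parameter point and refits with ``fit_kwargs`` (which should mirror —
    possibly at reduced settings — the original fit).  Failed replicate
    fits are logged and excluded.

    ``ci_method="percentile"`` returns the 2.5/97.5 percentiles of the
    replicate estimates; ``"basic"`` reflects them about the point
    estimate (``[2 theta - q97.5, 2 theta - q2.5]``), which corrects the
    first-order estimator bias that replicates inherit — relevant at
    heavily reduced fit settings, where the maximizer of the noisy
    composite likelihood is visibly biased.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    fit_kwargs = dict(fit_kwargs or {})
    ss = np.random.SeedSequence([int(rng_seed) & 0x7FFFFFFF, 0xB007])
    seeds = ss.generate_state(2 * n_boot)
    estimates: list[dict[str, float]] = []
    n_failed = 0
    for b in range(n_boot):
        try:
            boot_obs = simulate_observed_sfs(model, best_fit.params, n_snps,
                                             int(seeds[2 * b] >> 1))
            refit = fit_model(boot_obs, model,
                              rng_seed=int(seeds[2 * b + 1] >> 1), **fit_kwargs)
            estimates.append(refit.params)
        except Exception as exc:  # noqa: BLE001 - replicate failure is data
            warnings.warn(f"bootstrap replicate {b} failed: {exc}")
            n_failed += 1
    if not estimates:
        raise RuntimeError("all bootstrap replicates failed")
    names = model.param_names
    arr = {n: np.array([e[n] for e in estimates]) for n in names}
    ci = {}
    for n in names:
        q_lo, q_hi = (float(np.percentile(arr[n], 2.5)),
                      float(np.percentile(arr[n], 97.5)))
        if ci_method == "basic":
            theta = best_fit.params[n]
            ci[n] = (2 * theta - q_hi, 2 * theta - q_lo)
        elif ci_method == "percentile":
            ci[n] = (q_lo, q_hi)
        else:
            raise ValueError(f"unknown ci_method {ci_method!r}")
    return {"ci": ci, "distributions": arr, "n_failed": n_failed}
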