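"""Two-state HMM genome segmentation with beta-binomial emissions.

The genome is modelled as alternating stretches of LOW and HIGH
methylation.  Each covered cytosine contributes an observation
(n_meth, n_total); its sequence context (CG, CHG, CHH) selects which of
six beta-binomial emission parameter pairs scores it, so a single state
path is shared across contexts while each context keeps its own
methylation-rate distribution.  The beta-binomial captures both read
sampling (binomial given the latent per-site rate) and between-site
variability of that rate (beta-distributed), which is essential in plants
where CHG and CHH methylation is far from binary.

Training is Baum-Welch EM: transition/initial updates are expected-count
ratios; emission shape updates maximise the expected complete-data
log-likelihood numerically on (log alpha, log beta), warm-started from the
current values so the observed-data likelihood never decreases.

Decoding is by per-site posterior (forward-backward) by default; runs of
consecutive sites whose HIGH-state posterior clears a cutoff become
methylated regions (MRs).  Covered sites separated by more than a desert
distance are decoded as independent chains so the model never bridges
cytosine-free or unsequenced gaps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from numba import njit
from scipy.optimize import minimize
from scipy.special import betaln, gammaln

from .io_formats import CONTEXTS, ValidationError
from .methylome import SampleMethylome

STATE_LOW, STATE_HIGH = 0, 1
STATE_NAMES = ("LOW", "HIGH")
CTX_INDEX = {c: i for i, c in enumerate(CONTEXTS)}


class DomainError(ValueError):
    """Argument outside the mathematical domain of an operation."""


@dataclass(frozen=True)
class BetaBinomialParams:
    """Shape parameters of a beta-binomial distribution.

    The implied mean is alpha/(alpha+beta); the overdispersion
    (intraclass correlation) is 1/(1+alpha+beta).
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise DomainError(f"shapes must be positive, got ({self.alpha}, {self.beta})")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def dispersion(self) -> float:
        return 1.0 / (1.0 + self.alpha + self.beta)

    @classmethod
    def from_mean_dispersion(cls, mean: float, dispersion: float) -> "BetaBinomialParams":
        if not (0 < mean < 1 and 0 < dispersion < 1):
            raise DomainError("mean and dispersion must lie in (0, 1)")
        s = (1.0 - dispersion) / dispersion
        return cls(mean * s, (1.0 - mean) * s)


def bb_log_pmf(k, n, params: BetaBinomialParams):
    """Log pmf of the beta-binomial, evaluated in log-gamma space.

    ``log C(n,k) + log B(k+alpha, n-k+beta) - log B(alpha, beta)``.
    Accepts scalars or arrays for ``k`` and ``n``; k=n=0 has probability 1.
    """
    k = np.asarray(k)
    n = np.asarray(n)
    if np.any(k < 0) or np.any(k > n):
        raise DomainError("require 0 <= k <= n")
    a, b = params.alpha, params.beta
    out = (
        gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
        + betaln(k + a, n - k + b) - betaln(a, b)
    )
    return out if out.ndim else float(out)


def _bb_log_pmf_raw(k, n, a, b):
    return (
        gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
        + betaln(k + a, n - k + b) - betaln(a, b)
    )


@dataclass
class HMMModel:
    """Two-state HMM with per-context beta-binomial emissions.

    ``emission[(state, context)]`` holds one of six shape pairs.  States
    are identified by the ordering constraint mean(HIGH) > mean(LOW) in
    every context.
    """

    initial: np.ndarray
    transition: np.ndarray
    emission: dict[tuple[int, str], BetaBinomialParams]

    def validate(self, require_ordering: bool = True) -> None:
        init = np.asarray(self.initial, dtype=float)
        trans = np.asarray(self.transition, dtype=float)
        if init.shape != (2,) or abs(init.sum() - 1.0) > 1e-9 or (init < 0).any():
            raise ValidationError("initial must be a length-2 probability vector")
        if trans.shape != (2, 2) or (trans < 0).any() or \
                np.abs(trans.sum(axis=1) - 1.0).max() > 1e-9:
            raise ValidationError("transition must be 2x2 row-stochastic")
        for ctx in CONTEXTS:
            for s in (STATE_LOW, STATE_HIGH):
                if (s, ctx) not in self.emission:
                    raise ValidationError(f"missing emission parameters for ({s}, {ctx})")
            if require_ordering:
                lo = self.emission[(STATE_LOW, ctx)].mean
                hi = self.emission[(STATE_HIGH, ctx)].mean
                if not hi > lo:
                    raise ValidationError(
                        f"state identifiability violated in {ctx}: "
                        f"mean(HIGH)={hi:.4f} <= mean(LOW)={lo:.4f}"
                    )

    def emission_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(alpha, beta) arrays of shape (2 states, 3 contexts)."""
        a = np.empty((2, 3))
        b = np.empty((2, 3))
        for (s, ctx), p in self.emission.items():
            a[s, CTX_INDEX[ctx]] = p.alpha
            b[s, CTX_INDEX[ctx]] = p.beta
        return a, b

    def relabelled(self) -> "HMMModel":
        """Swap state labels (LOW <-> HIGH) everywhere."""
        return HMMModel(
            initial=self.initial[::-1].copy(),
            transition=self.transition[::-1, ::-1].copy(),
            emission={(1 - s, c): p for (s, c), p in self.emission.items()},
        )

    @classmethod
    def default_init(cls) -> "HMMModel":
        """Deterministic initialisation used for training.

        LOW starts near mean 0.02 with dispersion 0.1, HIGH near mean 0.8
        with dispersion 0.2; self-transitions 0.99 (LOW) and 0.95 (HIGH);
        the initial distribution is the stationary distribution of that
        transition matrix.
        """
        trans = np.array([[0.99, 0.01], [0.05, 0.95]])
        init = np.array([5.0 / 6.0, 1.0 / 6.0])
        emission = {}
        for ctx in CONTEXTS:
            emission[(STATE_LOW, ctx)] = BetaBinomialParams.from_mean_dispersion(0.02, 0.1)
            emission[(STATE_HIGH, ctx)] = BetaBinomialParams.from_mean_dispersion(0.8, 0.2)
        return cls(init, trans, emission)

    def to_text(self, path) -> None:
        """Serialise as a plain-text key-value file (inspectable, reloadable)."""
        with open(path, "w") as fh:
            fh.write(f"initial\t{self.initial[0]:.12g}\t{self.initial[1]:.12g}\n")
            for i in range(2):
                fh.write(
                    f"transition_{STATE_NAMES[i]}\t{self.transition[i, 0]:.12g}\t"
                    f"{self.transition[i, 1]:.12g}\n"
                )
            for ctx in CONTEXTS:
                for s in (STATE_LOW, STATE_HIGH):
                    p = self.emission[(s, ctx)]
                    fh.write(f"emission_{ctx}_{STATE_NAMES[s]}\t{p.alpha:.12g}\t{p.beta:.12g}\n")

    @classmethod
    def from_text(cls, path) -> "HMMModel":
        init = None
        trans = np.empty((2, 2))
        emission: dict[tuple[int, str], BetaBinomialParams] = {}
        with open(path) as fh:
            for line in fh:
                key, v1, v2 = line.rstrip("\n").split("\t")
                if key == "initial":
                    init = np.array([float(v1), float(v2)])
                elif key.startswith("transition_"):
                    s = STATE_NAMES.index(key.split("_")[1])
                    trans[s] = [float(v1), float(v2)]
                elif key.startswith("emission_"):
                    _, ctx, sname = key.split("_")
                    emission[(STATE_NAMES.index(sname), ctx)] = BetaBinomialParams(
                        float(v1), float(v2)
                    )
        model = cls(init, trans, emission)
        model.validate(require_ordering=False)
        return model


# ---------------------------------------------------------------------------
# observation chains


@dataclass
class ObservationChain:
    """One contiguous run of covered cytosines decoded as a unit."""

    chrom: str
    pos: np.ndarray
    k: np.ndarray
    n: np.ndarray
    ctx: np.ndarray  # int codes into CONTEXTS


def chains_from_methylome(
    methylome: SampleMethylome, desert_distance: int = 2000
) -> list[ObservationChain]:
    """Split a methylome into observation chains at cytosine deserts.

    Consecutive covered sites farther apart than ``desert_distance`` bp
    break the sequence; chains are decoded independently so homogeneous
    transitions are never applied across unsequenced gaps.
    """
    chains = []
    for chrom, df in methylome.per_chrom():
        pos = df["pos"].to_numpy()
        k = df["n_meth"].to_numpy()
        n = df["n_total"].to_numpy()
        ctx = np.array([CTX_INDEX[c] for c in df["context"]], dtype=np.int64)
        if len(pos) == 0:
            continue
        breaks = np.flatnonzero(np.diff(pos) > desert_distance) + 1
        for seg in np.split(np.arange(len(pos)), breaks):
            chains.append(ObservationChain(chrom, pos[seg], k[seg], n[seg], ctx[seg]))
    return chains


# ---------------------------------------------------------------------------
# forward-backward (scaled, numba-compiled)


@njit(cache=True)
def _fb_kernel(e, start, trans):
    """Scaled forward-backward for one chain.

    ``e`` is the per-position emission likelihood matrix (T, 2), already
    rescaled so each row's maximum is 1 (the caller accounts for the
    offsets in the log-likelihood).  Returns (sum of log scale factors,
    posteriors gamma, expected transition counts xi, gamma at t=0).
    """
    T = e.shape[0]
    fwd = np.empty((T, 2))
    c = np.empty(T)
    for j in range(2):
        fwd[0, j] = start[j] * e[0, j]
    c[0] = fwd[0, 0] + fwd[0, 1]
    fwd[0, 0] /= c[0]
    fwd[0, 1] /= c[0]
    for t in range(1, T):
        for j in range(2):
            fwd[t, j] = (fwd[t - 1, 0] * trans[0, j] + fwd[t - 1, 1] * trans[1, j]) * e[t, j]
        c[t] = fwd[t, 0] + fwd[t, 1]
        fwd[t, 0] /= c[t]
        fwd[t, 1] /= c[t]
    bwd = np.empty((T, 2))
    bwd[T - 1, 0] = 1.0
    bwd[T - 1, 1] = 1.0
    xi = np.zeros((2, 2))
    for t in range(T - 2, -1, -1):
        b0 = e[t + 1, 0] * bwd[t + 1, 0]
        b1 = e[t + 1, 1] * bwd[t + 1, 1]
        for i in range(2):
            bwd[t, i] = (trans[i, 0] * b0 + trans[i, 1] * b1) / c[t + 1]
            xi[i, 0] += fwd[t, i] * trans[i, 0] * b0 / c[t + 1]
            xi[i, 1] += fwd[t, i] * trans[i, 1] * b1 / c[t + 1]
    gamma = np.empty((T, 2))
    for t in range(T):
        g0 = fwd[t, 0] * bwd[t, 0]
        g1 = fwd[t, 1] * bwd[t, 1]
        z = g0 + g1
        gamma[t, 0] = g0 / z
        gamma[t, 1] = g1 / z
    loglik_scale = 0.0
    for t in range(T):
        loglik_scale += np.log(c[t])
    gamma0 = np.empty(2)
    gamma0[0] = gamma[0, 0]
    gamma0[1] = gamma[0, 1]
    return loglik_scale, gamma, xi, gamma0


@njit(cache=True)
def _viterbi_kernel(loge, logstart, logtrans):
    T = loge.shape[0]
    delta = np.empty((T, 2))
    back = np.zeros((T, 2), dtype=np.int64)
    for j in range(2):
        delta[0, j] = logstart[j] + loge[0, j]
    for t in range(1, T):
        for j in range(2):
            best = delta[t - 1, 0] + logtrans[0, j]
            arg = 0
            alt = delta[t - 1, 1] + logtrans[1, j]
            if alt > best:
                best = alt
                arg = 1
            delta[t, j] = best + loge[t, j]
            back[t, j] = arg
    path = np.empty(T, dtype=np.int64)
    path[T - 1] = 0 if delta[T - 1, 0] >= delta[T - 1, 1] else 1
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path


def _log_emissions(chain: ObservationChain, model: HMMModel) -> np.ndarray:
    a, b = model.emission_arrays()
    loge = np.empty((len(chain.k), 2))
    for s in (STATE_LOW, STATE_HIGH):
        loge[:, s] = _bb_log_pmf_raw(chain.k, chain.n, a[s, chain.ctx], b[s, chain.ctx])
    return loge


def _run_fb(chain: ObservationChain, model: HMMModel):
    loge = _log_emissions(chain, model)
    offsets = loge.max(axis=1)
    e = np.exp(loge - offsets[:, None])
    scale, gamma, xi, gamma0 = _fb_kernel(
        e, np.asarray(model.initial, dtype=float), np.asarray(model.transition, dtype=float)
    )
    return float(scale + offsets.sum()), gamma, xi, gamma0


def forward_backward(
    observations: Sequence[tuple[int, int, str]] | ObservationChain, model: HMMModel
) -> tuple[float, np.ndarray]:
    """Log-likelihood and per-position state posteriors for one chain.

    ``observations`` is a sequence of (n_meth, n_total, context) triples
    (or an :class:`ObservationChain`).  Computation uses per-position
    scaling, so sequences of millions of sites do not underflow.
    """
    model.validate(require_ordering=False)
    if not isinstance(observations, ObservationChain):
        if len(observations) == 0:
            raise ValueError("empty observation sequence")
        k = np.array([o[0] for o in observations])
        n = np.array([o[1] for o in observations])
        ctx = np.array([CTX_INDEX[o[2]] for o in observations])
        observations = ObservationChain("", np.arange(len(k)), k, n, ctx)
    elif len(observations.k) == 0:
        raise ValueError("empty observation sequence")
    if np.any(observations.k > observations.n) or np.any(observations.k < 0):
        raise DomainError("require 0 <= n_meth <= n_total")
    loglik, gamma, _, _ = _run_fb(observations, model)
    return loglik, gamma


# ---------------------------------------------------------------------------
# Baum-Welch EM


@dataclass
class BaumWelchResult:
    model: HMMModel
    loglik_trace: list[float]
    converged: bool
    warnings: list[str] = field(default_factory=list)

    @property
    def no_high_state_support(self) -> bool:
        return "no high state support" in self.warnings


def _weighted_bb_mle(k, n, w, start_params: BetaBinomialParams,
                     extra_starts: Iterable[BetaBinomialParams] = ()):
    """Maximise sum(w * bb_log_pmf(k, n)) over the shape parameters.

    Bounded quasi-Newton on (log alpha, log beta); the warm start at the
    current parameters guarantees the objective never worsens.
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    w = np.asarray(w, dtype=float)
    bounds = [(math.log(1e-6), math.log(1e6))] * 2

    def neg(x):
        a, b = math.exp(x[0]), math.exp(x[1])
        return -float(np.dot(w, _bb_log_pmf_raw(k, n, a, b)))

    best_x = np.array([math.log(start_params.alpha), math.log(start_params.beta)])
    best_x = np.clip(best_x, bounds[0][0], bounds[0][1])
    best_f = neg(best_x)
    starts = [best_x] + [
        np.clip([math.log(p.alpha), math.log(p.beta)], bounds[0][0], bounds[0][1])
        for p in extra_starts
    ]
    for x0 in starts:
        res = minimize(neg, x0, method="L-BFGS-B", bounds=bounds)
        if res.fun < best_f:
            best_f = res.fun
            best_x = res.x
    return BetaBinomialParams(math.exp(best_x[0]), math.exp(best_x[1])), -best_f


def _moment_params(k, n, w) -> BetaBinomialParams | None:
    """Method-of-moments shapes from (posterior-)weighted rates."""
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    w = np.asarray(w, dtype=float)
    tot = np.dot(w, n)
    if tot <= 0:
        return None
    m = np.dot(w, k) / tot
    m = min(max(m, 1e-4), 1 - 1e-4)
    p = k / n
    wsum = w.sum()
    if wsum <= 0:
        return None
    var = np.dot(w, (p - m) ** 2) / wsum
    base = m * (1 - m)
    rho = min(max((var / base) if base > 0 else 0.05, 1e-4), 0.95)
    return BetaBinomialParams.from_mean_dispersion(m, rho)


def baum_welch(
    chains: list[ObservationChain],
    init: HMMModel | None = None,
    max_iter: int = 100,
    tol: float = 1e-4,
    min_sites_per_context: int = 100,
) -> BaumWelchResult:
    """Train the segmentation HMM by expectation-maximisation.

    ``tol`` is the relative log-likelihood improvement below which
    training stops.  Contexts with fewer than ``min_sites_per_context``
    covered sites keep their initial emission parameters (with a warning);
    there is too little data to learn their rate distribution.  After
    training, states are relabelled if EM swapped them, so that the HIGH
    state has the larger emission mean.
    """
    if init is None:
        init = HMMModel.default_init()
    init.validate(require_ordering=False)
    if max_iter == 0:
        return BaumWelchResult(init, [], converged=False)
    chains = [c for c in chains if len(c.k) > 0]
    if not chains:
        raise ValueError("no observations to train on")

    warnings: list[str] = []
    # group identical (k, n) observations within each context: emission
    # updates then cost O(unique pairs) instead of O(sites)
    all_k = np.concatenate([c.k for c in chains])
    all_n = np.concatenate([c.n for c in chains])
    all_ctx = np.concatenate([c.ctx for c in chains])
    ctx_counts = np.bincount(all_ctx, minlength=3)
    trainable_ctx = ctx_counts >= min_sites_per_context
    for ci, ok in enumerate(trainable_ctx):
        if not ok:
            warnings.append(
                f"context {CONTEXTS[ci]}: {ctx_counts[ci]} sites < "
                f"{min_sites_per_context}; emissions kept at initialisation"
            )
    triples = np.stack([all_ctx, all_k, all_n], axis=1)
    uniq, group_id = np.unique(triples, axis=0, return_inverse=True)
    group_id = np.asarray(group_id).ravel()
    n_groups = len(uniq)
    u_ctx, u_k, u_n = uniq[:, 0], uniq[:, 1].astype(float), uniq[:, 2].astype(float)

    model = HMMModel(
        np.asarray(init.initial, float).copy(),
        np.asarray(init.transition, float).copy(),
        dict(init.emission),
    )
    trace: list[float] = []
    converged = False
    prev_ll = -np.inf
    for _ in range(max_iter):
        a_arr, b_arr = model.emission_arrays()
        # E-step: emission table over unique (ctx, k, n) groups
        log_table = np.empty((n_groups, 2))
        for s in (STATE_LOW, STATE_HIGH):
            log_table[:, s] = _bb_log_pmf_raw(u_k, u_n, a_arr[s, u_ctx], b_arr[s, u_ctx])
        ll = 0.0
        xi_sum = np.zeros((2, 2))
        gamma0_sum = np.zeros(2)
        w_group = np.zeros((n_groups, 2))
        offset = 0
        for chain in chains:
            T = len(chain.k)
            gid = group_id[offset : offset + T]
            loge = log_table[gid]
            offs = loge.max(axis=1)
            e = np.exp(loge - offs[:, None])
            scale, gamma, xi, gamma0 = _fb_kernel(e, model.initial, model.transition)
            ll += scale + offs.sum()
            xi_sum += xi
            gamma0_sum += gamma0
            np.add.at(w_group[:, 0], gid, gamma[:, 0])
            np.add.at(w_group[:, 1], gid, gamma[:, 1])
            offset += T
        trace.append(float(ll))
        if np.isfinite(prev_ll) and (ll - prev_ll) < tol * abs(prev_ll):
            converged = True
            break
        prev_ll = ll

        # M-step
        model.initial = gamma0_sum / gamma0_sum.sum()
        row = xi_sum.sum(axis=1)
        new_trans = model.transition.copy()
        for i in range(2):
            if row[i] > 0:
                new_trans[i] = xi_sum[i] / row[i]
        model.transition = new_trans
        emission = dict(model.emission)
        for ci, ctx in enumerate(CONTEXTS):
            if not trainable_ctx[ci]:
                continue
            mask = u_ctx == ci
            for s in (STATE_LOW, STATE_HIGH):
                w = w_group[mask, s]
                if w.sum() < 1e-8:
                    continue
                cur = emission[(s, ctx)]
                mom = _moment_params(u_k[mask], u_n[mask], w)
                extra = [mom] if mom is not None else []
                emission[(s, ctx)], _ = _weighted_bb_mle(
                    u_k[mask], u_n[mask], w, cur, extra
                )
        model.emission = emission

    # relabel so HIGH carries the larger mean, weighting contexts by data
    weights = ctx_counts / max(ctx_counts.sum(), 1)
    mean_by_state = [
        sum(weights[ci] * model.emission[(s, ctx)].mean for ci, ctx in enumerate(CONTEXTS))
        for s in (STATE_LOW, STATE_HIGH)
    ]
    if mean_by_state[STATE_HIGH] < mean_by_state[STATE_LOW]:
        model = model.relabelled()

    # degenerate data: no support for a high-methylation state
    a_arr, b_arr = model.emission_arrays()
    log_table = np.empty((n_groups, 2))
    for s in (STATE_LOW, STATE_HIGH):
        log_table[:, s] = _bb_log_pmf_raw(u_k, u_n, a_arr[s, u_ctx], b_arr[s, u_ctx])
    high_occ = 0.0
    offset = 0
    for chain in chains:
        T = len(chain.k)
        loge = log_table[group_id[offset : offset + T]]
        offs = loge.max(axis=1)
        e = np.exp(loge - offs[:, None])
        _, gamma, _, _ = _fb_kernel(e, model.initial, model.transition)
        high_occ += gamma[:, 1].sum()
        offset += T
    if high_occ < 1.0 or all_k.sum() == 0:
        warnings.append("no high state support")

    try:
        model.validate(require_ordering=True)
    except ValidationError as exc:
        warnings.append(f"mean ordering not satisfied in all contexts: {exc}")
    return BaumWelchResult(model, trace, converged, warnings)


# ---------------------------------------------------------------------------
# decoding


@dataclass
class MethylatedRegion:
    """A contiguous high-methylation interval in one sample (0-based,
    half-open); start/end span the first to last member cytosine."""

    sample_id: str
    chrom: str
    start: int
    end: int
    n_sites: dict[str, int]
    sum_meth: dict[str, int]
    sum_total: dict[str, int]
    mean_posterior: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError("MR must have end > start")

    @property
    def total_sites(self) -> int:
        return sum(self.n_sites.values())


def decode_regions(
    methylome: SampleMethylome,
    model: HMMModel,
    posterior_cutoff: float = 0.5,
    min_sites: int = 5,
    desert_distance: int = 2000,
    method: str = "posterior",
) -> list[MethylatedRegion]:
    """Decode a methylome into methylated regions.

    Maximal runs of consecutive covered sites whose HIGH-state posterior
    reaches ``posterior_cutoff`` become MRs; runs with fewer than
    ``min_sites`` covered cytosines are discarded.  ``method='viterbi'``
    replaces the posterior rule with the best single state path.
    """
    if not (0.5 <= posterior_cutoff < 1.0):
        raise ValueError("posterior_cutoff must lie in [0.5, 1)")
    try:
        model.validate(require_ordering=True)
    except ValidationError as exc:
        raise ValidationError(
            f"refusing to decode with an untrained/degenerate model: {exc}"
        ) from exc

    regions: list[MethylatedRegion] = []
    for chain in chains_from_methylome(methylome, desert_distance):
        if method == "viterbi":
            loge = _log_emissions(chain, model)
            path = _viterbi_kernel(
                loge,
                np.log(np.asarray(model.initial, float) + 1e-300),
                np.log(np.asarray(model.transition, float) + 1e-300),
            )
            high = path == STATE_HIGH
            post = high.astype(float)
        else:
            _, gamma = forward_backward(chain, model)
            post = gamma[:, STATE_HIGH]
            high = post >= posterior_cutoff
        if not high.any():
            continue
        padded = np.concatenate([[False], high, [False]])
        starts = np.flatnonzero(~padded[:-1] & padded[1:])
        ends = np.flatnonzero(padded[:-1] & ~padded[1:])
        for i0, i1 in zip(starts, ends):
            if i1 - i0 < min_sites:
                continue
            idx = slice(i0, i1)
            n_sites = {c: 0 for c in CONTEXTS}
            sum_meth = {c: 0 for c in CONTEXTS}
            sum_total = {c: 0 for c in CONTEXTS}
            for ci, ctx in enumerate(CONTEXTS):
                mask = chain.ctx[idx] == ci
                n_sites[ctx] = int(mask.sum())
                sum_meth[ctx] = int(chain.k[idx][mask].sum())
                sum_total[ctx] = int(chain.n[idx][mask].sum())
            regions.append(
                MethylatedRegion(
                    sample_id=methylome.sample_id,
                    chrom=chain.chrom,
                    start=int(chain.pos[i0]),
                    end=int(chain.pos[i1 - 1]) + 1,
                    n_sites=n_sites,
                    sum_meth=sum_meth,
                    sum_total=sum_total,
                    mean_posterior=float(post[idx].mean()),
                )
            )
    regions.sort(key=lambda r: (r.chrom, r.start))
    return regions


def train_models(
    methylomes: Mapping[str, SampleMethylome],
    mode: str = "per_sample",
    reference: str | None = None,
    desert_distance: int = 2000,
    **bw_kwargs,
) -> dict[str, BaumWelchResult]:
    """Train segmentation models for a cohort.

    ``per_sample`` trains one model per sample on its own data;
    ``reference_sample`` trains once on the named sample and applies that
    model to everyone (useful when some samples have globally perturbed
    methylation that would distort their own training).
    """
    if mode not in ("per_sample", "reference_sample"):
        raise ValueError(f"unknown training mode {mode!r}")
    if mode == "reference_sample":
        if reference is None or reference not in methylomes:
            raise ValueError(f"reference sample {reference!r} not in cohort")
        result = baum_welch(
            chains_from_methylome(methylomes[reference], desert_distance), **bw_kwargs
        )
        return {sid: result for sid in methylomes}
    return {
        sid: baum_welch(chains_from_methylome(m, desert_distance), **bw_kwargs)
        for sid, m in methylomes.items()
    }
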