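"""Non-homogeneous two-state HMM over CpGs on cfDNA fragments.

The hidden state of every CpG on every fragment is unmethylated (U) or
methylated (M). The chain is non-homogeneous: the initiation vector is
binned by the first CpG's offset from the fragment start, and each
transition matrix is binned by the genomic distance to the previous
CpG. Emissions are the three z-scored fragmentation features, each
modelled per state by a two-component Gaussian mixture (features
conditionally independent given the state):

    Pr(e | state) = prod_f [ (1-pi_f) N(mu_i, s_i^2) + pi_f N(mu_j, s_j^2) ]

Training is unsupervised Baum-Welch (max 50 iterations, fragments with
>= 7 CpGs), initialised by a diagonal-covariance Gaussian mixture over
all CpG observations; convergence is monitored by a sampled, symmetrised
Kullback-Leibler divergence between successive models (10,000 fragments
with >= 5 CpGs; converged when D < 1e-4 or D changes by < 1%).

At decoding, a per-CpG methylation prior k (healthy buffy-coat WGBS)
enters through the posterior emission

    Pr(m | e) = Pr(e|m) k / (Pr(e|m) k + Pr(e|u) (1-k))

and Viterbi / forward-backward run on these posterior terms. The prior
is used only at decoding, never during training.

`FragmentMethylationHMM` follows the scikit-learn estimator protocol
(get_params/set_params, fit, predict), in the spirit of hmmlearn.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator
from sklearn.mixture import GaussianMixture

from .errors import DegenerateModelError, NumericalError, UsageError
from .features import FEATURE_NAMES, CpGObservation, Fragment

logger = logging.getLogger(__name__)

STATE_U, STATE_M = 0, 1
STATE_NAMES = ("U", "M")

LOG_EPS = -745.0  # below exp underflow

DEFAULT_DISTANCE_EDGES = (10, 20, 50, 100, 200, 500)
DEFAULT_OFFSET_EDGES = (25, 50, 75, 100, 150)

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class DistanceBins:
    """Bin layouts for inter-CpG distances and first-CpG offsets.

    ``distance_edges`` (d1 < d2 < ...) define bins (0, d1], (d1, d2],
    ..., (dk, inf); ``offset_edges`` the same for the first CpG's offset
    with bins starting at offset 0: [0, o1], (o1, o2], ..., (ok, inf).
    """

    distance_edges: tuple[int, ...] = DEFAULT_DISTANCE_EDGES
    offset_edges: tuple[int, ...] = DEFAULT_OFFSET_EDGES

    def __post_init__(self) -> None:
        for edges in (self.distance_edges, self.offset_edges):
            if any(b <= a for a, b in zip(edges, edges[1:])):
                raise UsageError("bin edges must be strictly increasing")

    @property
    def n_distance_bins(self) -> int:
        return len(self.distance_edges) + 1

    @property
    def n_offset_bins(self) -> int:
        return len(self.offset_edges) + 1

    def distance_bin(self, d) -> np.ndarray:
        return np.searchsorted(self.distance_edges, d, side="left")

    def offset_bin(self, o) -> np.ndarray:
        return np.searchsorted(self.offset_edges, o, side="left")


@dataclass
class MethylationPrior:
    """Per-CpG methylation prior track with a genome-wide default."""

    k: dict[tuple[str, int], float] = field(default_factory=dict)
    default_k: float = 0.5
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.weight <= 1.0):
            raise UsageError("prior weight must be in [0, 1]")

    def get(self, chrom: str, position: int) -> float:
        return self.k.get((chrom, position), self.default_k)

    def effective(self, chrom: str, position: int) -> float:
        """Prior shrunk toward 1/2 by the prior weight: k' = w k + (1-w)/2."""
        k = self.get(chrom, position)
        return self.weight * k + (1.0 - self.weight) * 0.5

    @classmethod
    def from_bedgraph(cls, path: str, weight: float = 1.0) -> "MethylationPrior":
        """Load chrom/start/_/level rows; default_k = track mean."""
        k: dict[tuple[str, int], float] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track")):
                    continue
                parts = line.split("\t")
                chrom, start, value = parts[0], int(parts[1]), float(parts[3])
                k[(chrom, start)] = min(max(value, 0.0), 1.0)
        default = float(np.mean(list(k.values()))) if k else 0.5
        return cls(k=k, default_k=default, weight=weight)


@dataclass
class DecodedFragment:
    """Viterbi path and forward-backward posteriors for one fragment."""

    fragment: Fragment
    path: np.ndarray  # int {0,1} per observation
    posterior_m: np.ndarray  # Pr(M) per observation
    loglik: float

    @property
    def path_string(self) -> str:
        return "".join(STATE_NAMES[s] for s in self.path)


# ---------------------------------------------------------------------------
# low-level densities


def _log_normal(x: np.ndarray, mean: np.ndarray, var: np.ndarray) -> np.ndarray:
    return -0.5 * (np.log(2.0 * np.pi * var) + (x - mean) ** 2 / var)


def _log_mixture(x, weight, means, variances):
    """log[(1-pi) N(mu_i, s_i^2) + pi N(mu_j, s_j^2)] elementwise."""
    a = np.log1p(-weight + 1e-300) + _log_normal(x, means[..., 0], variances[..., 0])
    b = np.log(weight + 1e-300) + _log_normal(x, means[..., 1], variances[..., 1])
    return np.logaddexp(a, b)


def posterior_emission(log_lik_u: float, log_lik_m: float, k: float, w: float = 1.0):
    """Posterior-adjusted emission probabilities (Pr(u|e), Pr(m|e)).

    Combines state-conditional likelihoods with the effective prior
    k' = w k + (1-w)/2 in log space, so simultaneous underflow of both
    likelihoods never yields 0/0.
    """
    if not (0.0 <= k <= 1.0):
        raise UsageError("prior k must be in [0, 1]")
    k_eff = w * k + (1.0 - w) * 0.5
    if k_eff <= 0.0:
        return 1.0, 0.0
    if k_eff >= 1.0:
        return 0.0, 1.0
    lm = log_lik_m + np.log(k_eff)
    lu = log_lik_u + np.log1p(-k_eff)
    norm = np.logaddexp(lm, lu)
    # symmetric evaluation so exact ties stay exact
    pu = float(np.exp(lu - norm))
    pm = float(np.exp(lm - norm))
    total = pu + pm
    return pu / total, pm / total


# ---------------------------------------------------------------------------
# packed fragment batches


class _Batch:
    """Padded arrays for vectorised forward-backward over many fragments."""

    def __init__(self, fragments: Sequence[Fragment], bins: DistanceBins):
        self.fragments = fragments
        lengths = np.array([f.n_cpgs for f in fragments], dtype=np.int64)
        if lengths.size == 0 or lengths.min() < 1:
            raise UsageError("fragments must have at least one CpG observation")
        self.lengths = lengths
        self.T = int(lengths.max())
        F = len(fragments)
        self.Z = np.zeros((F, self.T, 3))
        self.dbin = np.zeros((F, self.T), dtype=np.int64)
        self.obin = np.zeros(F, dtype=np.int64)
        for i, f in enumerate(fragments):
            zs = [o.z for o in f.observations]
            if any(z is None for z in zs):
                raise UsageError("observations must be z-scored before the HMM")
            arr = np.asarray(zs)
            if not np.isfinite(arr).all():
                raise NumericalError("non-finite feature value in fragment batch")
            n = f.n_cpgs
            self.Z[i, :n] = arr
            self.obin[i] = bins.offset_bin(f.observations[0].offset)
            for t in range(1, n):
                self.dbin[i, t] = bins.distance_bin(f.observations[t].distance_to_prev)
        self.mask = np.arange(self.T)[None, :] < lengths[:, None]


def _batch_log_emission(batch: _Batch, weights, means, variances) -> np.ndarray:
    """(F, T, 2) log emission likelihoods for padded observations."""
    F, T, _ = batch.Z.shape
    out = np.zeros((F, T, 2))
    for s in range(2):
        per_feature = _log_mixture(
            batch.Z, weights[s][None, None, :], means[s][None, None, :, :],
            variances[s][None, None, :, :],
        )
        out[:, :, s] = per_feature.sum(axis=2)
    return out


def _batch_forward_backward(batch: _Batch, log_start, log_trans, logB):
    """Vectorised FB. Returns (loglik[F], gamma[F,T,2], xi_num[F,T,2,2]).

    ``xi_num[:, t]`` holds the joint posterior of (state t-1, state t);
    rows t >= length are zero.
    """
    F, T, _ = logB.shape
    la = np.full((F, T, 2), -np.inf)
    la[:, 0, :] = log_start[batch.obin] + logB[:, 0, :]
    for t in range(1, T):
        act = batch.mask[:, t]
        if not act.any():
            break
        prev = la[act, t - 1, :]
        trans = log_trans[batch.dbin[act, t]]  # (f, 2, 2)
        la[act, t, :] = logsumexp(prev[:, :, None] + trans, axis=1) + logB[act, t, :]
    last = batch.lengths - 1
    loglik = logsumexp(la[np.arange(F), last, :], axis=1)
    if not np.isfinite(loglik).all():
        raise NumericalError("non-finite fragment log-likelihood")

    lb = np.full((F, T, 2), -np.inf)
    lb[np.arange(F), last, :] = 0.0
    for t in range(T - 2, -1, -1):
        act = batch.mask[:, t + 1]
        nxt = lb[act, t + 1, :] + logB[act, t + 1, :]
        trans = log_trans[batch.dbin[act, t + 1]]
        lb[act, t, :] = logsumexp(trans + nxt[:, None, :], axis=2)

    with np.errstate(invalid="ignore"):
        gamma = np.exp(la + lb - loglik[:, None, None])
    gamma[~batch.mask] = 0.0

    xi = np.zeros((F, T, 2, 2))
    for t in range(1, T):
        act = batch.mask[:, t]
        if not act.any():
            break
        trans = log_trans[batch.dbin[act, t]]
        num = (
            la[act, t - 1, :, None]
            + trans
            + (logB[act, t, :] + lb[act, t, :])[:, None, :]
            - loglik[act, None, None]
        )
        xi[act, t] = np.exp(num)
    return loglik, gamma, xi


# ---------------------------------------------------------------------------
# the estimator


class FragmentMethylationHMM(BaseEstimator):
    """Non-homogeneous two-state HMM over cfDNA fragments.

    Parameters
    ----------
    distance_edges, offset_edges
        Bin edges for the transition distance bins and initiation offset
        bins (bp).
    max_iter
        Baum-Welch iteration cap (default 50).
    min_cpgs_train
        Minimum CpGs per fragment for a fragment to enter training
        (default 7).
    kl_sample, kl_min_cpgs
        Size and minimum CpG count of the fragment sample used for the
        KL convergence statistic (defaults 10,000 and 5).
    kl_tol, kl_rel_tol
        Convergence fires when the sampled KL divergence between
        successive models falls below ``kl_tol`` (1e-4) or changes by
        less than ``kl_rel_tol`` (1%) relative to the previous iteration.
    gmm_max_iter
        EM cap for the initialising Gaussian mixture (default 10,000).
    mode
        'wgs': the mixture component with the larger mean z-scored
        distance-to-center is labelled methylated; 'wgbs': labels come
        from mean fragment-level truth states.
    pseudocount
        Added to every binned initiation/transition count.
    var_floor
        Lower bound on mixture variances (z^2 units).
    random_state
        Seed for GMM initialisation and KL sampling.

    Fitted attributes (trailing underscore) include ``startprob_``
    (offset-bin x state), ``transmat_`` (distance-bin x 2 x 2),
    ``emission_weights_ / emission_means_ / emission_vars_``
    (state x feature [x component]), ``converged_``, ``n_iter_`` and
    per-iteration ``history_``.
    """

    def __init__(
        self,
        distance_edges: tuple[int, ...] = DEFAULT_DISTANCE_EDGES,
        offset_edges: tuple[int, ...] = DEFAULT_OFFSET_EDGES,
        max_iter: int = 50,
        min_cpgs_train: int = 7,
        kl_sample: int = 10000,
        kl_min_cpgs: int = 5,
        kl_tol: float = 1e-4,
        kl_rel_tol: float = 0.01,
        kl_min_iter: int = 5,
        gmm_max_iter: int = 10000,
        mode: str = "wgs",
        pseudocount: float = 1.0,
        var_floor: float = 1e-4,
        random_state: int | None = None,
    ):
        self.distance_edges = distance_edges
        self.offset_edges = offset_edges
        self.max_iter = max_iter
        self.min_cpgs_train = min_cpgs_train
        self.kl_sample = kl_sample
        self.kl_min_cpgs = kl_min_cpgs
        self.kl_tol = kl_tol
        self.kl_rel_tol = kl_rel_tol
        self.kl_min_iter = kl_min_iter
        self.gmm_max_iter = gmm_max_iter
        self.mode = mode
        self.pseudocount = pseudocount
        self.var_floor = var_floor
        self.random_state = random_state

    # -- construction helpers -------------------------------------------------

    @property
    def bins_(self) -> DistanceBins:
        return DistanceBins(tuple(self.distance_edges), tuple(self.offset_edges))

    @classmethod
    def from_parameters(
        cls,
        startprob: np.ndarray,
        transmat: np.ndarray,
        emission_weights: np.ndarray,
        emission_means: np.ndarray,
        emission_vars: np.ndarray,
        distance_edges: tuple[int, ...] = DEFAULT_DISTANCE_EDGES,
        offset_edges: tuple[int, ...] = DEFAULT_OFFSET_EDGES,
        **params,
    ) -> "FragmentMethylationHMM":
        """Build a ready-to-decode model from explicit parameter arrays."""
        model = cls(distance_edges=distance_edges, offset_edges=offset_edges, **params)
        model._set_state(
            np.asarray(startprob, float),
            np.asarray(transmat, float),
            np.asarray(emission_weights, float),
            np.asarray(emission_means, float),
            np.asarray(emission_vars, float),
        )
        model.converged_ = True
        model.n_iter_ = 0
        model.history_ = []
        return model

    def _set_state(self, startprob, transmat, weights, means, variances) -> None:
        bins = self.bins_
        if startprob.shape != (bins.n_offset_bins, 2):
            raise UsageError(f"startprob must be {(bins.n_offset_bins, 2)}")
        if transmat.shape != (bins.n_distance_bins, 2, 2):
            raise UsageError(f"transmat must be {(bins.n_distance_bins, 2, 2)}")
        if not np.allclose(startprob.sum(axis=1), 1.0, atol=1e-9):
            raise NumericalError("initiation vectors must sum to 1")
        if not np.allclose(transmat.sum(axis=2), 1.0, atol=1e-9):
            raise NumericalError("transition rows must sum to 1")
        self.startprob_ = startprob
        self.transmat_ = transmat
        self.emission_weights_ = weights  # (2, 3)
        self.emission_means_ = means  # (2, 3, 2)
        self.emission_vars_ = np.maximum(variances, self.var_floor)
        self.feature_names_ = FEATURE_NAMES

    def _check_fitted(self) -> None:
        if not hasattr(self, "startprob_"):
            raise UsageError("model is not fitted; call fit() or load a model file")

    # -- log parameter views --------------------------------------------------

    @property
    def _log_start(self) -> np.ndarray:
        return np.log(np.maximum(self.startprob_, np.exp(LOG_EPS)))

    @property
    def _log_trans(self) -> np.ndarray:
        return np.log(np.maximum(self.transmat_, np.exp(LOG_EPS)))

    # -- GMM initialisation ---------------------------------------------------

    def _gmm_initialize(self, fragments: Sequence[Fragment], rng: np.random.Generator):
        Z = np.asarray([o.z for f in fragments for o in f.observations])
        if np.unique(Z, axis=0).shape[0] < 2:
            raise DegenerateModelError("need >= 2 distinct observation vectors")
        labels = None
        for attempt in range(10):
            seed = int(rng.integers(0, 2**31 - 1))
            gm = GaussianMixture(
                n_components=2,
                covariance_type="diag",
                max_iter=self.gmm_max_iter,
                random_state=seed,
                reg_covar=self.var_floor,
                n_init=1,
            )
            cand = gm.fit_predict(Z)
            if 0 < cand.sum() < cand.size:
                labels = cand
                break
        if labels is None:
            raise DegenerateModelError("GMM produced an empty component repeatedly")
        return Z, labels

    def _label_components(
        self, fragments: Sequence[Fragment], Z: np.ndarray, labels: np.ndarray
    ) -> np.ndarray:
        """Relabel GMM components so that 1 = methylated.

        wgs: larger mean z-scored distance-to-center is methylated;
        wgbs: larger mean truth methylation is methylated. Exact ties
        fall back to the longer mean fragment length.
        """
        if self.mode == "wgbs":
            truth = []
            for f in fragments:
                states = f.truth_states or [None] * f.n_cpgs
                truth.extend(1.0 if s == "M" else (0.0 if s == "U" else np.nan) for s in states)
            truth_arr = np.asarray(truth)
            crit = np.array(
                [np.nanmean(truth_arr[labels == c]) if np.isfinite(truth_arr[labels == c]).any()
                 else np.nan for c in (0, 1)]
            )
        elif self.mode == "wgs":
            crit = np.array([Z[labels == c, 2].mean() for c in (0, 1)])
        else:
            raise UsageError(f"mode must be 'wgs' or 'wgbs', got {self.mode!r}")
        if not np.isfinite(crit).all() or crit[0] == crit[1]:
            logger.warning("component labelling tie; falling back to mean fragment length")
            crit = np.array([Z[labels == c, 0].mean() for c in (0, 1)])
        m_component = int(np.argmax(crit))
        return (labels == m_component).astype(int)

    def _initial_parameters(self, fragments: Sequence[Fragment], states: np.ndarray):
        """Count-based initiation/transition estimates and moment-split
        emission mixtures from hard state assignments."""
        bins = self.bins_
        start = np.full((bins.n_offset_bins, 2), self.pseudocount)
        trans = np.full((bins.n_distance_bins, 2, 2), self.pseudocount)
        idx = 0
        for f in fragments:
            n = f.n_cpgs
            s = states[idx : idx + n]
            start[bins.offset_bin(f.observations[0].offset), s[0]] += 1
            for t in range(1, n):
                b = bins.distance_bin(f.observations[t].distance_to_prev)
                trans[b, s[t - 1], s[t]] += 1
            idx += n
        start /= start.sum(axis=1, keepdims=True)
        trans /= trans.sum(axis=2, keepdims=True)

        Z = np.asarray([o.z for f in fragments for o in f.observations])
        weights = np.full((2, 3), 0.5)
        means = np.zeros((2, 3, 2))
        variances = np.ones((2, 3, 2))
        for s in range(2):
            sub = Z[states == s]
            m = sub.mean(axis=0)
            sd = np.maximum(sub.std(axis=0), np.sqrt(self.var_floor))
            # split each feature into symmetric half-SD components,
            # preserving the total variance
            means[s, :, 0] = m - 0.5 * sd
            means[s, :, 1] = m + 0.5 * sd
            variances[s, :, :] = (0.75 * sd**2)[:, None]
        return start, trans, weights, means, variances

    # -- likelihood pieces ----------------------------------------------------

    def emission_loglik(self, observation: CpGObservation, state: int) -> float:
        """Log emission density of one z-scored observation under a state."""
        self._check_fitted()
        z = observation.z
        if z is None or not np.isfinite(z).all():
            raise NumericalError("observation not z-scored or non-finite")
        val = _log_mixture(
            np.asarray(z),
            self.emission_weights_[state],
            self.emission_means_[state],
            self.emission_vars_[state],
        ).sum()
        return float(val)

    def _fragment_logB(self, fragment: Fragment, prior: MethylationPrior | None):
        """(n, 2) per-CpG log 'emission' terms used at decoding.

        With a prior these are the Eq.-style posterior probabilities;
        without one, the uniform-prior posterior (normalised likelihood).
        """
        n = fragment.n_cpgs
        out = np.zeros((n, 2))
        for t, obs in enumerate(fragment.observations):
            lu = self.emission_loglik(obs, STATE_U)
            lm = self.emission_loglik(obs, STATE_M)
            if prior is None:
                k, w = 0.5, 1.0
            else:
                k, w = prior.get(fragment.chrom, obs.ref_position), prior.weight
            pu, pm = posterior_emission(lu, lm, k, w)
            out[t, 0] = np.log(pu) if pu > 0 else LOG_EPS
            out[t, 1] = np.log(pm) if pm > 0 else LOG_EPS
        return out

    def score_fragments(self, fragments: Sequence[Fragment]) -> np.ndarray:
        """Prior-free forward log-likelihood of each fragment."""
        self._check_fitted()
        batch = _Batch(fragments, self.bins_)
        logB = _batch_log_emission(
            batch, self.emission_weights_, self.emission_means_, self.emission_vars_
        )
        loglik, _, _ = _batch_forward_backward(batch, self._log_start, self._log_trans, logB)
        return loglik

    def score(self, fragments: Sequence[Fragment], y=None) -> float:
        return float(np.mean(self.score_fragments(fragments)))

    # -- training -------------------------------------------------------------

    def fit(self, fragments: Sequence[Fragment], y=None) -> "FragmentMethylationHMM":
        """GMM-initialise then Baum-Welch-train on fragments with
        >= ``min_cpgs_train`` CpGs."""
        rng = np.random.default_rng(self.random_state)
        train = [f for f in fragments if f.n_cpgs >= self.min_cpgs_train]
        if not train:
            raise UsageError(
                f"no fragment has >= {self.min_cpgs_train} CpGs; reduce min_cpgs_train"
            )
        Z, raw_labels = self._gmm_initialize(train, rng)
        states = self._label_components(train, Z, raw_labels)
        self._set_state(*self._initial_parameters(train, states))
        self.gmm_states_ = states
        return self._baum_welch(train, rng)

    def _baum_welch(
        self, train: Sequence[Fragment], rng: np.random.Generator
    ) -> "FragmentMethylationHMM":
        bins = self.bins_
        batch = _Batch(train, bins)
        kl_pool = [f for f in train if f.n_cpgs >= self.kl_min_cpgs]
        sample_idx = rng.choice(
            len(kl_pool), size=min(self.kl_sample, len(kl_pool)), replace=False
        ) if kl_pool else np.empty(0, dtype=int)
        kl_batch = _Batch([kl_pool[i] for i in sample_idx], bins) if kl_pool else None

        self.history_ = []
        self.converged_ = False
        self.n_iter_ = 0
        prev_D = None
        for iteration in range(self.max_iter):
            old = self._snapshot()
            logB = _batch_log_emission(
                batch, self.emission_weights_, self.emission_means_, self.emission_vars_
            )
            loglik, gamma, xi = _batch_forward_backward(
                batch, self._log_start, self._log_trans, logB
            )
            total_ll = float(loglik.sum())
            if not np.isfinite(total_ll):
                raise NumericalError(f"non-finite training log-likelihood at iter {iteration}")
            self._m_step(batch, gamma, xi)
            self.n_iter_ = iteration + 1

            D = self._kl_between(old, self._snapshot(), kl_batch)
            reason = None
            # the relative-change rule only applies once past the burn-in
            # iterations: EM can cross slow saddles early whose D is
            # momentarily flat but far from converged
            if D < self.kl_tol:
                reason = "kl_abs"
            elif (
                iteration + 1 >= self.kl_min_iter
                and prev_D is not None
                and prev_D > 0
                and abs(D - prev_D) / prev_D < self.kl_rel_tol
            ):
                reason = "kl_rel"
            self.history_.append(
                {"iteration": iteration, "loglik": total_ll, "kl": float(D),
                 "converged_reason": reason}
            )
            prev_D = D
            if reason is not None:
                self.converged_ = True
                logger.info("converged at iteration %d (%s, D=%.3g)", iteration, reason, D)
                break
        return self

    def _snapshot(self) -> dict:
        return {
            "startprob": self.startprob_.copy(),
            "transmat": self.transmat_.copy(),
            "weights": self.emission_weights_.copy(),
            "means": self.emission_means_.copy(),
            "vars": self.emission_vars_.copy(),
        }

    def _restore(self, snap: dict) -> None:
        self._set_state(
            snap["startprob"], snap["transmat"], snap["weights"], snap["means"], snap["vars"]
        )

    def _kl_between(self, snap_old: dict, snap_new: dict, kl_batch: _Batch | None) -> float:
        """Sampled symmetrised per-CpG KL divergence between two models."""
        if kl_batch is None or not kl_batch.fragments:
            raise UsageError("empty fragment sample for KL divergence")
        lls = []
        for snap in (snap_old, snap_new):
            logB = _batch_log_emission(kl_batch, snap["weights"], snap["means"], snap["vars"])
            ls = np.log(np.maximum(snap["startprob"], np.exp(LOG_EPS)))
            lt = np.log(np.maximum(snap["transmat"], np.exp(LOG_EPS)))
            ll, _, _ = _batch_forward_backward(kl_batch, ls, lt, logB)
            lls.append(ll / kl_batch.lengths)
        # the two directions' contributions have equal magnitude and
        # opposite sign, so their averaged absolute value is |mean diff|
        return float(abs(np.mean(lls[1] - lls[0])))

    def _m_step(self, batch: _Batch, gamma: np.ndarray, xi: np.ndarray) -> None:
        bins = self.bins_
        start = np.full((bins.n_offset_bins, 2), self.pseudocount)
        np.add.at(start, batch.obin, gamma[:, 0, :])
        start /= start.sum(axis=1, keepdims=True)

        trans = np.full((bins.n_distance_bins, 2, 2), self.pseudocount)
        for t in range(1, batch.T):
            act = batch.mask[:, t]
            if not act.any():
                break
            np.add.at(trans, batch.dbin[act, t], xi[act, t])
        trans /= trans.sum(axis=2, keepdims=True)

        Z = batch.Z[batch.mask]  # (N, 3)
        G = gamma[batch.mask]  # (N, 2)
        weights = self.emission_weights_.copy()
        means = self.emission_means_.copy()
        variances = self.emission_vars_.copy()
        for s in range(2):
            for f in range(3):
                x = Z[:, f]
                lw0 = np.log1p(-weights[s, f] + 1e-300) + _log_normal(
                    x, means[s, f, 0], variances[s, f, 0]
                )
                lw1 = np.log(weights[s, f] + 1e-300) + _log_normal(
                    x, means[s, f, 1], variances[s, f, 1]
                )
                norm = np.logaddexp(lw0, lw1)
                r1 = np.exp(lw1 - norm)
                w = G[:, s]
                denom = w.sum()
                for c, rc in ((0, 1.0 - r1), (1, r1)):
                    wc = w * rc
                    tot = wc.sum()
                    if tot < 1e-12:
                        continue  # keep the old component
                    mu = float((wc * x).sum() / tot)
                    var = float((wc * (x - mu) ** 2).sum() / tot)
                    means[s, f, c] = mu
                    variances[s, f, c] = max(var, self.var_floor)
                if denom > 0:
                    weights[s, f] = float(np.clip((w * r1).sum() / denom, 1e-6, 1 - 1e-6))
        self._set_state(start, trans, weights, means, variances)

    # -- decoding -------------------------------------------------------------

    def decode_fragment(
        self, fragment: Fragment, prior: MethylationPrior | None = None
    ) -> DecodedFragment:
        """Viterbi path plus forward-backward Pr(M) for one fragment.

        Viterbi ties are broken toward the previous state on the path
        (first CpG and final tie: toward M).
        """
        self._check_fitted()
        bins = self.bins_
        n = fragment.n_cpgs
        if n < 1:
            raise UsageError("cannot decode a fragment without CpGs")
        logB = self._fragment_logB(fragment, prior)
        ls, lt = self._log_start, self._log_trans
        obin = bins.offset_bin(fragment.observations[0].offset)

        delta = np.zeros((n, 2))
        psi = np.zeros((n, 2), dtype=int)
        delta[0] = ls[obin] + logB[0]
        for t in range(1, n):
            b = bins.distance_bin(fragment.observations[t].distance_to_prev)
            for s in range(2):
                cand = delta[t - 1] + lt[b, :, s]
                # tie -> continue from the same state
                best = s if cand[s] >= cand[1 - s] else 1 - s
                psi[t, s] = best
                delta[t, s] = cand[best] + logB[t, s]
        path = np.zeros(n, dtype=int)
        path[-1] = STATE_M if delta[-1, STATE_M] >= delta[-1, STATE_U] else STATE_U
        for t in range(n - 2, -1, -1):
            path[t] = psi[t + 1, path[t + 1]]

        # forward-backward on the same posterior-emission terms
        la = np.zeros((n, 2))
        la[0] = ls[obin] + logB[0]
        for t in range(1, n):
            b = bins.distance_bin(fragment.observations[t].distance_to_prev)
            la[t] = logsumexp(la[t - 1][:, None] + lt[b], axis=0) + logB[t]
        lb = np.zeros((n, 2))
        for t in range(n - 2, -1, -1):
            b = bins.distance_bin(fragment.observations[t + 1].distance_to_prev)
            lb[t] = logsumexp(lt[b] + (logB[t + 1] + lb[t + 1])[None, :], axis=1)
        ll = float(logsumexp(la[-1]))
        post = np.exp(la + lb - ll)
        return DecodedFragment(
            fragment=fragment, path=path, posterior_m=post[:, 1], loglik=ll
        )

    def predict(
        self, fragments: Sequence[Fragment], prior: MethylationPrior | None = None
    ) -> list[DecodedFragment]:
        """Decode every fragment (no minimum CpG count at decoding)."""
        return [self.decode_fragment(f, prior) for f in fragments]

    def predict_proba(
        self, fragments: Sequence[Fragment], prior: MethylationPrior | None = None
    ) -> list[np.ndarray]:
        return [d.posterior_m for d in self.predict(fragments, prior)]

    # -- serialization --------------------------------------------------------

    def to_json(self, path: str, feature_stats: dict | None = None) -> None:
        self._check_fitted()
        doc = {
            "format_version": MODEL_FORMAT_VERSION,
            "model": "non-homogeneous-2-state-cpg-hmm",
            "feature_names": list(FEATURE_NAMES),
            "distance_edges": list(self.distance_edges),
            "offset_edges": list(self.offset_edges),
            "startprob": self.startprob_.tolist(),
            "transmat": self.transmat_.tolist(),
            "emission_weights": self.emission_weights_.tolist(),
            "emission_means": self.emission_means_.tolist(),
            "emission_vars": self.emission_vars_.tolist(),
            "mode": self.mode,
            "n_iter": getattr(self, "n_iter_", 0),
            "converged": bool(getattr(self, "converged_", False)),
            "feature_stats": feature_stats,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "FragmentMethylationHMM":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("format_version") != MODEL_FORMAT_VERSION:
            raise UsageError(f"unsupported model format version {doc.get('format_version')}")
        model = cls.from_parameters(
            np.asarray(doc["startprob"]),
            np.asarray(doc["transmat"]),
            np.asarray(doc["emission_weights"]),
            np.asarray(doc["emission_means"]),
            np.asarray(doc["emission_vars"]),
            distance_edges=tuple(doc["distance_edges"]),
            offset_edges=tuple(doc["offset_edges"]),
            mode=doc.get("mode", "wgs"),
        )
        model.n_iter_ = doc.get("n_iter", 0)
        model.converged_ = doc.get("converged", False)
        model.feature_stats_ = doc.get("feature_stats")
        return model


# ---------------------------------------------------------------------------
# functional surface (thin wrappers)


def gmm_initialize(
    fragments: Sequence[Fragment],
    max_iter: int = 10000,
    seed: int | None = None,
    **params,
) -> tuple[np.ndarray, FragmentMethylationHMM]:
    """Fit the initialising GMM and return (state assignments, initial model).

    The returned model has count-based initiation/transition estimates
    and moment-split emission mixtures; components are already labelled
    (wgs rule by default).
    """
    model = FragmentMethylationHMM(gmm_max_iter=max_iter, random_state=seed, **params)
    rng = np.random.default_rng(seed)
    Z, raw = model._gmm_initialize(fragments, rng)
    states = model._label_components(fragments, Z, raw)
    model._set_state(*model._initial_parameters(fragments, states))
    return states, model


def baum_welch(
    fragments: Sequence[Fragment],
    model: FragmentMethylationHMM,
    seed: int | None = None,
) -> FragmentMethylationHMM:
    """Run Baum-Welch on an initialised model (in place; returns it)."""
    model._check_fitted()
    train = [f for f in fragments if f.n_cpgs >= model.min_cpgs_train]
    if not train:
        raise UsageError(
            f"no fragment has >= {model.min_cpgs_train} CpGs; reduce min_cpgs_train"
        )
    return model._baum_welch(train, np.random.default_rng(seed))


def kl_divergence(
    model_old: FragmentMethylationHMM,
    model_new: FragmentMethylationHMM,
    fragments: Sequence[Fragment],
) -> float:
    """Sampled symmetrised per-CpG KL divergence between two models."""
    model_old._check_fitted()
    model_new._check_fitted()
    if not fragments:
        raise UsageError("empty fragment sample for KL divergence")
    batch = _Batch(fragments, model_old.bins_)
    return model_old._kl_between(model_old._snapshot(), model_new._snapshot(), batch)


def viterbi_decode(
    fragment: Fragment,
    model: FragmentMethylationHMM,
    prior: MethylationPrior | None = None,
) -> DecodedFragment:
    return model.decode_fragment(fragment, prior)


def assign_state_labels(
    model: FragmentMethylationHMM,
    mode: str,
    fragments: Sequence[Fragment],
    assignments: np.ndarray,
) -> np.ndarray:
    """Relabel anonymous component assignments so that 1 = methylated."""
    model.mode = mode
    Z = np.asarray([o.z for f in fragments for o in f.observations])
    return model._label_components(fragments, Z, assignments)
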