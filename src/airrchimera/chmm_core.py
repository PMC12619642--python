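"""The chimera-detecting hidden Markov model.

Model
-----
For G germline references and K discretized mutation rates the HMM has
2·G·K states: G·K "non-chimeric" states (set U, the path has never switched
template) duplicated into G·K "chimeric" states (set C, the path switched at
least once).  State index = half·G·K + ref·K + rate, with the non-chimeric
half first.  The initial distribution is uniform over U.  Per column, a path
stays in its state with probability 1−ψ−μ, moves to another mutation-rate
state of the same reference (same half) with probability μ/(K−1) each, and
switches reference with probability ψ/((G−1)K) per target state — landing
only in the chimeric half, so any path ending in U never switched.
Emissions compare the query nucleotide with the state's reference
nucleotide: 1−m on a match, m/3 on a mismatch, and 1 when either side is a
gap or N (such columns carry no information).

The chimera posterior is the forward mass of the chimeric half of the final
lattice column divided by the total.  The structured transition matrix lets
forward, backward and Viterbi run in O(L·G·K) instead of O(L·(GK)²): the
incoming sums (or maxima) decompose into a self term, a per-reference term
and a global term, each precomputable once per column.

All public operations accept a single threaded query; batched variants
(``forward_many``, ``baum_welch_many``) evaluate whole repertoires with the
same arithmetic and are what the detection pipeline uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import (
    DatabaseTooSmallError,
    InvalidCharacterError,
    LatticeError,
    ModeError,
    ParameterError,
)
from .reference_db import ReferenceMSA, encode_sequence

_EMIT_FLAT = 0  # either side gap/N: emission 1
_EMIT_MATCH = 1  # emission 1 - m
_EMIT_MISMATCH = 2  # emission m / 3


@dataclass
class HMMSpec:
    """HMM parameters: the reference MSA, the mutation-rate categories, and
    the per-column switching rates ψ (reference switch, chimera formation)
    and μ (rate-category switch within a reference).

    For DB mode ``rates`` is the shared grid of K rates; for BW mode K must
    be 1 and ``ref_rates`` may hold fitted per-reference rates.
    """

    msa: ReferenceMSA
    rates: np.ndarray
    psi: float = 0.002
    mu: float = 0.002
    mode: str = "DB"
    ref_rates: np.ndarray | None = None

    def __post_init__(self):
        self.rates = np.atleast_1d(np.asarray(self.rates, dtype=float))
        if self.rates.ndim != 1 or self.rates.size < 1:
            raise ParameterError("rates must be a non-empty 1-D sequence")
        if ((self.rates < 0) | (self.rates >= 0.5)).any():
            raise ParameterError("mutation rates must lie in [0, 0.5)")
        if self.mode not in ("DB", "BW"):
            raise ParameterError(f"mode must be 'DB' or 'BW', got {self.mode!r}")
        if self.mode == "BW" and self.K != 1:
            raise ModeError("BW mode requires K = 1")
        if self.psi < 0 or self.mu < 0 or self.psi + self.mu >= 1:
            raise ParameterError("need psi >= 0, mu >= 0 and psi + mu < 1")
        if self.msa.G < 2:
            raise DatabaseTooSmallError("HMM needs at least 2 references")
        if self.ref_rates is not None:
            self.ref_rates = np.asarray(self.ref_rates, dtype=float)
            if self.ref_rates.shape != (self.G,):
                raise ParameterError("ref_rates must have shape (G,)")

    @property
    def G(self) -> int:
        return self.msa.G

    @property
    def K(self) -> int:
        return int(self.rates.size)

    @property
    def L(self) -> int:
        return self.msa.L

    @property
    def n_states(self) -> int:
        return 2 * self.G * self.K

    @property
    def mu_eff(self) -> float:
        """μ as actually used: with K = 1 there is no rate category to switch
        to, the μ term vanishes and self-transitions keep that mass."""
        return self.mu if self.K > 1 else 0.0

    def rate_matrix(self) -> np.ndarray:
        """(G, K) mutation rates per reference and category."""
        if self.ref_rates is not None:
            return self.ref_rates[:, None]
        return np.broadcast_to(self.rates, (self.G, self.K))


@dataclass
class ForwardResult:
    """Forward-pass output: total log-likelihood log P(O) and the chimera
    posterior P(chimera | O).  ``alpha``/``scales`` hold the per-column
    rescaled lattice when requested (needed by backward and Baum-Welch)."""

    log_likelihood: float
    chimera_posterior: float
    alpha: np.ndarray | None = None
    scales: np.ndarray | None = None


@dataclass
class ViterbiResult:
    """Most probable state path, its log joint probability, the reference
    switches as (from_allele, to_allele, breakpoint_column) events, and the
    reference names visited in path order."""

    state_path: np.ndarray
    log_prob: float
    events: list[tuple[str, str, int]]
    path_refs: list[str]


# ---------------------------------------------------------------------------
# encoding and emissions


def _query_codes(query) -> np.ndarray:
    seq = query.columns if hasattr(query, "columns") else str(query)
    return encode_sequence(seq)


def _emission_classes(obs: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """(n, G, L) int8 class matrix: flat / match / mismatch per query,
    reference and column.  Gap or N on either side is class 'flat'."""
    o = obs[:, None, :]
    r = ref[None, :, :]
    return np.where(
        (o >= 4) | (r >= 4),
        _EMIT_FLAT,
        np.where(o == r, _EMIT_MATCH, _EMIT_MISMATCH),
    ).astype(np.int8)


def _emissions(cls_t: np.ndarray, rates_b: np.ndarray) -> np.ndarray:
    """Emission probabilities for one column.

    cls_t : (n, G) class codes; rates_b broadcastable to (n, G, K).
    Returns (n, G, K)."""
    c = cls_t[:, :, None]
    return np.where(c == _EMIT_MATCH, 1.0 - rates_b,
                    np.where(c == _EMIT_MISMATCH, rates_b / 3.0, 1.0))


def emission_prob(ref_nt: str, obs_nt: str, m: float) -> float:
    """Single-site emission probability.

    1−m if the observation matches the reference nucleotide, m/3 on a
    nucleotide mismatch, and 1 whenever the observation or the reference is
    a gap or N (no information either way).
    """
    valid = set("ACGT-N")
    if obs_nt not in valid or ref_nt not in valid:
        raise InvalidCharacterError(
            f"nucleotides must be one of A,C,G,T,-,N; got ref={ref_nt!r} "
            f"obs={obs_nt!r}"
        )
    if not (0 <= m < 1):
        raise ParameterError(f"mutation rate must be in [0, 1), got {m}")
    if obs_nt in "-N" or ref_nt in "-N":
        return 1.0
    return 1.0 - m if obs_nt == ref_nt else m / 3.0


# ---------------------------------------------------------------------------
# linear-time forward / backward


def _coefs(spec: HMMSpec) -> tuple[float, float, float]:
    G, K = spec.G, spec.K
    stay = 1.0 - spec.psi - spec.mu_eff
    rate_coef = spec.mu / (K - 1) if K > 1 else 0.0
    cross_coef = spec.psi / ((G - 1) * K)
    return stay, rate_coef, cross_coef


def forward_many(
    obs_codes: np.ndarray,
    spec: HMMSpec,
    *,
    per_query_rates: np.ndarray | None = None,
    return_lattice: bool = False,
    chunk_size: int = 1024,
) -> tuple[np.ndarray, np.ndarray] | tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Scaled forward pass over a batch of encoded queries.

    Parameters
    ----------
    obs_codes : (n, L) uint8 query codes.
    per_query_rates : optional (n, G) per-query per-reference rates (K must
        be 1); overrides the spec's rate matrix.  Used by Baum-Welch.

    Returns ``(posterior, log_likelihood)`` arrays of shape (n,), plus the
    scaled lattice ``(n, L, 2, G, K)`` and scales ``(n, L)`` when
    ``return_lattice`` is set (in which case the batch is not chunked by the
    caller's chunk_size — lattices are concatenated).
    """
    obs_codes = np.atleast_2d(np.asarray(obs_codes, dtype=np.uint8))
    n, L = obs_codes.shape
    if L != spec.L:
        raise LatticeError(f"query length {L} != MSA column count {spec.L}")
    if per_query_rates is not None and spec.K != 1:
        raise ModeError("per-query rates require K = 1")
    G, K = spec.G, spec.K
    post = np.empty(n)
    loglik = np.empty(n)
    lattices, scales_all = [], []
    for lo in range(0, n, chunk_size):
        hi = min(lo + chunk_size, n)
        chunk = obs_codes[lo:hi]
        pq = per_query_rates[lo:hi] if per_query_rates is not None else None
        out = _forward_chunk(chunk, spec, pq, return_lattice)
        post[lo:hi], loglik[lo:hi] = out[0], out[1]
        if return_lattice:
            lattices.append(out[2])
            scales_all.append(out[3])
    if return_lattice:
        return post, loglik, np.concatenate(lattices), np.concatenate(scales_all)
    return post, loglik


def _forward_chunk(obs, spec, per_query_rates, return_lattice):
    n, L = obs.shape
    G, K = spec.G, spec.K
    stay, rate_coef, cross_coef = _coefs(spec)
    cls = _emission_classes(obs, spec.msa.codes)
    if per_query_rates is not None:
        rates_b = per_query_rates[:, :, None]
    else:
        rates_b = spec.rate_matrix()[None, :, :]

    alpha = np.zeros((n, 2, G, K))
    alpha[:, 0] = _emissions(cls[:, :, 0], rates_b) / (G * K)
    s = alpha.sum(axis=(1, 2, 3))
    if (s <= 0).any():
        raise LatticeError("query has zero likelihood under the model")
    alpha /= s[:, None, None, None]
    loglik = np.log(s)
    if return_lattice:
        lattice = np.empty((n, L, 2, G, K))
        scales = np.empty((n, L))
        lattice[:, 0] = alpha
        scales[:, 0] = s
    for t in range(1, L):
        # after rescaling the total alpha mass is exactly 1
        ref_half = alpha.sum(axis=3)  # (n, 2, G)
        new = alpha * stay
        if K > 1:
            new += (ref_half[:, :, :, None] - alpha) * rate_coef
        ref_both = ref_half.sum(axis=1)  # (n, G)
        new[:, 1] += ((1.0 - ref_both) * cross_coef)[:, :, None]
        new *= _emissions(cls[:, :, t], rates_b)[:, None, :, :]
        s = new.sum(axis=(1, 2, 3))
        if (s <= 0).any():
            raise LatticeError("query has zero likelihood under the model")
        alpha = new / s[:, None, None, None]
        loglik += np.log(s)
        if return_lattice:
            lattice[:, t] = alpha
            scales[:, t] = s
    post = alpha[:, 1].sum(axis=(1, 2))
    if return_lattice:
        return post, loglik, lattice, scales
    return post, loglik


def forward(query, spec: HMMSpec, *, return_lattice: bool = False) -> ForwardResult:
    """Linear-time forward pass for one threaded query (or raw MSA-space
    string).  Returns the chimera posterior and log-likelihood."""
    codes = _query_codes(query)[None, :]
    if return_lattice:
        post, ll, lattice, scales = forward_many(
            codes, spec, return_lattice=True
        )
        return ForwardResult(float(ll[0]), float(post[0]), lattice[0], scales[0])
    post, ll = forward_many(codes, spec)
    return ForwardResult(float(ll[0]), float(post[0]))


def backward_many(
    obs_codes: np.ndarray,
    spec: HMMSpec,
    scales: np.ndarray,
    *,
    per_query_rates: np.ndarray | None = None,
) -> np.ndarray:
    """Scaled backward lattice (n, L, 2, G, K) matching ``forward_many``'s
    scaling convention: sum_i alpha_t(i)·beta_t(i) = 1 at every column."""
    obs_codes = np.atleast_2d(np.asarray(obs_codes, dtype=np.uint8))
    n, L = obs_codes.shape
    if L != spec.L:
        raise LatticeError(f"query length {L} != MSA column count {spec.L}")
    G, K = spec.G, spec.K
    stay, rate_coef, cross_coef = _coefs(spec)
    cls = _emission_classes(obs_codes, spec.msa.codes)
    if per_query_rates is not None:
        rates_b = per_query_rates[:, :, None]
    else:
        rates_b = spec.rate_matrix()[None, :, :]
    beta = np.empty((n, L, 2, G, K))
    beta[:, L - 1] = 1.0
    cur = beta[:, L - 1]
    for t in range(L - 2, -1, -1):
        w = _emissions(cls[:, :, t + 1], rates_b)[:, None, :, :] * cur
        w_ref_half = w.sum(axis=3)  # (n, 2, G)
        wc_ref = w_ref_half[:, 1]  # chimeric half, per reference
        wc_tot = wc_ref.sum(axis=1)
        nxt = w * stay
        if K > 1:
            nxt += (w_ref_half[:, :, :, None] - w) * rate_coef
        # any state can switch into the chimeric states of other references
        nxt += ((wc_tot[:, None] - wc_ref) * cross_coef)[:, None, :, None]
        nxt /= scales[:, t + 1][:, None, None, None]
        beta[:, t] = nxt
        cur = nxt
    return beta


def backward(query, spec: HMMSpec) -> np.ndarray:
    """Scaled backward lattice (L, 2, G, K) for one query, consistent with
    the forward scaling so that sum_i alpha_t(i) beta_t(i) = 1 per column."""
    codes = _query_codes(query)[None, :]
    _, _, _, scales = forward_many(codes, spec, return_lattice=True)
    return backward_many(codes, spec, scales)[0]


# ---------------------------------------------------------------------------
# dense oracle


def dense_transition_matrix(spec: HMMSpec) -> np.ndarray:
    """The full (2GK, 2GK) transition matrix implied by the structured
    model.  Every row sums to 1; used by the quadratic reference
    implementation and by tests."""
    G, K = spec.G, spec.K
    n = 2 * G * K
    stay, rate_coef, cross_coef = _coefs(spec)
    half = np.arange(n) // (G * K)
    ref = (np.arange(n) // K) % G
    A = np.zeros((n, n))
    same_ref = ref[:, None] == ref[None, :]
    same_half = half[:, None] == half[None, :]
    to_chimeric = half[None, :] == 1
    A[same_ref & same_half] = rate_coef
    A[~same_ref & np.broadcast_to(to_chimeric, (n, n))] = cross_coef
    np.fill_diagonal(A, stay)
    if not np.allclose(A.sum(axis=1), 1.0, atol=1e-12):
        raise LatticeError("transition matrix rows do not sum to 1")
    return A


def forward_oracle(query, spec: HMMSpec) -> ForwardResult:
    """Quadratic dense-matrix forward pass; identical contract to
    ``forward``.  Reference implementation for small instances."""
    codes = _query_codes(query)
    if codes.size != spec.L:
        raise LatticeError(
            f"query length {codes.size} != MSA column count {spec.L}"
        )
    G, K = spec.G, spec.K
    A = dense_transition_matrix(spec)
    cls = _emission_classes(codes[None, :], spec.msa.codes)[0]  # (G, L)
    rates = spec.rate_matrix()  # (G, K)

    def b_col(t):
        c = cls[:, t][:, None]
        bgk = np.where(c == _EMIT_MATCH, 1.0 - rates,
                       np.where(c == _EMIT_MISMATCH, rates / 3.0, 1.0))
        return np.concatenate([bgk.ravel(), bgk.ravel()])

    pi = np.zeros(2 * G * K)
    pi[: G * K] = 1.0 / (G * K)
    alpha = pi * b_col(0)
    s = alpha.sum()
    if s <= 0:
        raise LatticeError("query has zero likelihood under the model")
    alpha /= s
    loglik = np.log(s)
    for t in range(1, spec.L):
        alpha = (alpha @ A) * b_col(t)
        s = alpha.sum()
        if s <= 0:
            raise LatticeError("query has zero likelihood under the model")
        alpha /= s
        loglik += np.log(s)
    return ForwardResult(float(loglik), float(alpha[G * K:].sum()))


# ---------------------------------------------------------------------------
# Viterbi


def viterbi(query, spec: HMMSpec, *, per_ref_rates: np.ndarray | None = None) -> ViterbiResult:
    """Most probable state path in O(L·G·K) via per-column precomputation of
    the best and second-best scores (per reference-and-half for the μ term,
    per reference for the ψ term), so each state's best predecessor outside
    its own reference is available in O(1).  Ties break toward the lowest
    predecessor state index.  Breakpoints are the first 1-based MSA column
    held by the new reference.
    """
    codes = _query_codes(query)
    if codes.size != spec.L:
        raise LatticeError(
            f"query length {codes.size} != MSA column count {spec.L}"
        )
    G, K, L = spec.G, spec.K, spec.L
    stay, rate_coef, cross_coef = _coefs(spec)
    if per_ref_rates is not None:
        if spec.K != 1:
            raise ModeError("per-reference rates require K = 1")
        rates = np.asarray(per_ref_rates, dtype=float)[:, None]
    else:
        rates = spec.rate_matrix()
    cls = _emission_classes(codes[None, :], spec.msa.codes)[0]  # (G, L)

    with np.errstate(divide="ignore"):
        lstay = np.log(stay)
        lrate = np.log(rate_coef) if K > 1 else -np.inf
        lcross = np.log(cross_coef) if spec.psi > 0 else -np.inf

    def logb(t):
        c = cls[:, t][:, None]
        with np.errstate(divide="ignore"):
            return np.log(
                np.where(c == _EMIT_MATCH, 1.0 - rates,
                         np.where(c == _EMIT_MISMATCH, rates / 3.0, 1.0))
            )  # (G, K)

    delta = np.full((2, G, K), -np.inf)
    delta[0] = logb(0) - np.log(G * K)
    # flat state index = half*G*K + ref*K + rate
    flat_idx = np.arange(2 * G * K).reshape(2, G, K)
    backptr = np.empty((L, 2, G, K), dtype=np.int64)
    backptr[0] = -1
    NEG = -np.inf
    BIG = 2 * G * K + 1
    for t in range(1, L):
        cand_vals = []
        cand_preds = []
        # self transition
        cand_vals.append(delta + lstay)
        cand_preds.append(np.broadcast_to(flat_idx, (2, G, K)))
        if K > 1:
            # best same-reference same-half predecessor with a different rate
            top1k = delta.argmax(axis=2)  # first occurrence = lowest rate idx
            top1v = np.take_along_axis(delta, top1k[..., None], axis=2)[..., 0]
            masked = delta.copy()
            np.put_along_axis(masked, top1k[..., None], NEG, axis=2)
            top2k = masked.argmax(axis=2)
            top2v = np.take_along_axis(masked, top2k[..., None], axis=2)[..., 0]
            kk = np.arange(K)
            use_top1 = kk[None, None, :] != top1k[..., None]
            best_v = np.where(use_top1, top1v[..., None], top2v[..., None])
            best_k = np.where(use_top1, top1k[..., None], top2k[..., None])
            hh = np.arange(2)[:, None, None]
            gg = np.arange(G)[None, :, None]
            cand_vals.append(best_v + lrate)
            cand_preds.append(hh * G * K + gg * K + best_k)
        # best predecessor of a *different* reference (enters chimeric half)
        by_ref = delta.transpose(1, 0, 2).reshape(G, 2 * K)  # state-index order
        rb_arg = by_ref.argmax(axis=1)
        rb_val = by_ref[np.arange(G), rb_arg]
        order = np.argsort(-rb_val, kind="stable")
        r1, v1 = int(order[0]), rb_val[order[0]]
        if G > 1:
            r2, v2 = int(order[1]), rb_val[order[1]]
        else:  # pragma: no cover - G >= 2 enforced
            r2, v2 = r1, v1
        cross_v = np.where(np.arange(G) == r1, v2, v1)  # (G,)
        cross_r = np.where(np.arange(G) == r1, r2, r1)
        # flat predecessor index within the chosen reference
        pred_half = rb_arg[cross_r] // K
        pred_k = rb_arg[cross_r] % K
        cross_pred = pred_half * G * K + cross_r * K + pred_k  # (G,)
        cv = np.full((2, G, K), NEG)
        cp = np.full((2, G, K), BIG, dtype=np.int64)
        cv[1] = (cross_v + lcross)[:, None]
        cp[1] = cross_pred[:, None]
        cand_vals.append(cv)
        cand_preds.append(cp)

        V = np.stack(cand_vals)  # (ncand, 2, G, K)
        P = np.stack([np.broadcast_to(p, (2, G, K)) for p in cand_preds])
        best = V.max(axis=0)
        tie = V == best
        P_masked = np.where(tie, P, BIG)
        pred = P_masked.min(axis=0)
        delta = best + logb(t)[None, :, :]
        backptr[t] = pred

    flat_final = delta.reshape(-1)
    end_state = int(flat_final.argmax())  # first occurrence = lowest index
    log_prob = float(flat_final[end_state])
    path = np.empty(L, dtype=np.int64)
    path[L - 1] = end_state
    for t in range(L - 1, 0, -1):
        h, rem = divmod(path[t], G * K)
        g, k = divmod(rem, K)
        path[t - 1] = backptr[t, h, g, k]
    refs = (path // K) % G
    names = spec.msa.names
    events = []
    path_refs = [names[int(refs[0])]]
    for t in range(1, L):
        if refs[t] != refs[t - 1]:
            events.append((names[int(refs[t - 1])], names[int(refs[t])], t + 1))
            path_refs.append(names[int(refs[t])])
    return ViterbiResult(
        state_path=path, log_prob=log_prob, events=events, path_refs=path_refs
    )


# ---------------------------------------------------------------------------
# Baum-Welch (BW mode)


def baum_welch_many(
    obs_codes: np.ndarray,
    spec: HMMSpec,
    init_rate: float = 0.05,
    max_iter: int = 10,
    tol: float = 1e-3,
    *,
    chunk_size: int = 256,
    return_history: bool = False,
):
    """Per-query Baum-Welch re-estimation of a continuous per-reference
    mutation rate (K = 1; two states per germline).

    Each EM iteration runs the scaled forward/backward pass at the current
    rates and replaces each reference's rate with its expected mismatch
    fraction: posterior-occupancy-weighted mismatch emissions over
    informative emissions (columns where query and reference are both
    unambiguous nucleotides), pooling that reference's chimeric and
    non-chimeric states.  Rates are clamped to [1e-6, 0.5]; a query stops
    updating once its largest rate change drops below ``tol``.

    Returns ``(rates (n, G), posterior (n,), log_likelihood (n,))`` — plus a
    per-iteration log-likelihood history list when ``return_history`` is set.
    """
    if spec.K != 1:
        raise ModeError("Baum-Welch re-estimation requires K = 1")
    if not (0 < init_rate < 0.5):
        raise ParameterError(f"init_rate must be in (0, 0.5), got {init_rate}")
    obs_codes = np.atleast_2d(np.asarray(obs_codes, dtype=np.uint8))
    n, L = obs_codes.shape
    if L != spec.L:
        raise LatticeError(f"query length {L} != MSA column count {spec.L}")
    G = spec.G
    rates = np.full((n, G), float(init_rate))
    posterior = np.empty(n)
    loglik = np.empty(n)
    history: list[np.ndarray] = []
    for lo in range(0, n, chunk_size):
        hi = min(lo + chunk_size, n)
        chunk = obs_codes[lo:hi]
        m = hi - lo
        cls = _emission_classes(chunk, spec.msa.codes)  # (m, G, L)
        mism = cls == _EMIT_MISMATCH
        informative = mism | (cls == _EMIT_MATCH)
        r = rates[lo:hi]
        active = np.ones(m, dtype=bool)
        chunk_hist = []
        for _ in range(max_iter):
            post, ll, lattice, scales = forward_many(
                chunk, spec, per_query_rates=r, return_lattice=True,
                chunk_size=m,
            )
            chunk_hist.append(ll.copy())
            if not active.any():
                break
            beta = backward_many(chunk, spec, scales, per_query_rates=r)
            gamma = (lattice * beta).sum(axis=2)[..., 0]  # (m, L, G) both halves
            gamma = np.moveaxis(gamma, 1, 2)  # (m, G, L)
            num = (gamma * mism).sum(axis=2)
            den = (gamma * informative).sum(axis=2)
            with np.errstate(invalid="ignore", divide="ignore"):
                new = np.where(den > 0, num / np.maximum(den, 1e-300), r)
            new = np.clip(new, 1e-6, 0.5)
            delta = np.abs(new - r).max(axis=1)
            new = np.where(active[:, None], new, r)
            r = new
            active &= delta >= tol
        post, ll = forward_many(chunk, spec, per_query_rates=r, chunk_size=m)
        rates[lo:hi] = r
        posterior[lo:hi] = post
        loglik[lo:hi] = ll
        chunk_hist.append(ll.copy())
        history.append(chunk_hist)
    if return_history:
        return rates, posterior, loglik, history
    return rates, posterior, loglik


def baum_welch_rates(
    query,
    spec: HMMSpec,
    init_rate: float = 0.05,
    max_iter: int = 10,
    tol: float = 1e-3,
    *,
    return_history: bool = False,
):
    """Single-query BW fit.  Returns ``(rates (G,), ForwardResult)``; with
    ``return_history`` also the per-iteration log-likelihoods (monotone
    non-decreasing, an EM ascent)."""
    codes = _query_codes(query)[None, :]
    rates, post, ll, hist = baum_welch_many(
        codes, spec, init_rate, max_iter, tol, return_history=True
    )
    result = ForwardResult(float(ll[0]), float(post[0]))
    if return_history:
        traj = [float(x[0]) for x in hist[0]]
        return rates[0], result, traj
    return rates[0], result


def posterior_threshold(result, threshold: float) -> bool:
    """Call a query chimeric iff its posterior strictly exceeds the
    threshold (default pipeline threshold: 0.95)."""
    if not (0 < threshold < 1):
        raise ParameterError(f"threshold must be in (0, 1), got {threshold}")
    p = getattr(result, "chimera_posterior", result)
    return bool(p > threshold)
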