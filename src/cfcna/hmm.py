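"""Mixture HMM for joint tumor-fraction / copy-number estimation.

The observation for bin *i* is its normalized log2 ratio.  A hidden state
is an integer tumor copy number (clonal) or a copy number carried at a
shared cellular prevalence ``s`` (subclonal).  The expected log2 ratio of a
state under tumor fraction ``alpha`` and tumor ploidy ``phi_t`` is

    log2( (alpha*c_eff + (1-alpha)*phi_n) / (alpha*phi_t + (1-alpha)*phi_n) )

with ``c_eff = s*c_t + (1-s)*phi_n`` for subclonal states and ``c_t``
otherwise.  Emissions are Student's-t around the state mean with a shared
variance; parameters are fitted by EM over a grid of restarts, then
solutions are filtered by subclonal-genome-fraction rules and ranked by
log-likelihood, and finally a detection gate zeroes the tumor fraction of
profiles without credible alterations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

from .genome import BinTrack, _runs

LOG_RATIO_FLOOR = 2.0 ** -8


@dataclass(frozen=True)
class HMMState:
    label: str
    copy_number: int
    subclonal: bool = False

    @property
    def altered(self) -> bool:
        return self.subclonal or self.copy_number != 2


@dataclass(frozen=True)
class HMMConfig:
    """Estimator settings.

    ``ulp_profile``/``deep_profile`` provide the two published parameter
    sets: the deep profile lowers ``min_segment_bins`` from 50 to 20 and
    ``alt_frac_threshold`` from 0.05 to 0.01.
    """

    txn_e: float = 0.99
    txn_strength: float = 100.0
    normal_restarts: tuple[float, ...] = (0.5, 0.6, 0.7, 0.8, 0.9, 0.95)
    ploidy_restarts: tuple[float, ...] = (2.0, 3.0)
    max_cn: int = 5
    subclonal_cn: tuple[int, ...] = (1, 3)
    t_df: float = 2.1
    em_tol: float = 1e-4
    max_iter: int = 50
    min_segment_bins: int = 50
    alt_frac_threshold: float = 0.05
    alpha_bounds: tuple[float, float] = (0.0, 0.95)
    ploidy_bounds: tuple[float, float] = (1.5, 4.2)
    # Lower bound keeps subclonal states distinguishable from neutral;
    # letting s approach 0 lets them degenerate into extra noise states.
    s_bounds: tuple[float, float] = (0.3, 0.95)
    scalar_tol: float = 1e-5
    normal_ploidy: float = 2.0
    # Initial-state weight on the neutral (CN2) state used during fitting.
    # When the tumor fraction is near zero all state means collapse and the
    # chain-level assignment becomes arbitrary; starting chains from the
    # neutral state keeps uninformative chromosomes neutral.
    neutral_kappa: float = 50.0
    # Gaussian prior sd on tumor ploidy around each restart's init value;
    # treats restarts as hypotheses rather than free drift.  Without it a
    # small ploidy drift shifts every state mean slightly off zero and
    # near-zero-tumor-fraction fits absorb noise into spurious segments.
    ploidy_prior_sd: float = 0.2
    # Solutions whose log-likelihood is within this window of the best are
    # statistically indistinguishable; the least-altered one is selected
    # (a reproducible stand-in for manual inspection of ranked solutions).
    ll_tie_window: float = 6.0
    # A coherent solution's fitted ploidy matches the genome-average called
    # tumor copy number; relabeled (ploidy-shifted) degenerate fits do not.
    max_ploidy_discordance: float = 0.25
    max_subclone_genome_frac: float = 0.7
    max_subclonal_genome_frac: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.txn_e < 1.0:
            raise ValueError("txn_e must be in (0, 1)")
        if any(not 0.0 < f < 1.0 for f in self.normal_restarts):
            raise ValueError("restart fractions must be in (0, 1)")
        if not self.ploidy_restarts:
            raise ValueError("need at least one ploidy restart")

    @classmethod
    def ulp_profile(cls, **overrides) -> "HMMConfig":
        return cls(**{"min_segment_bins": 50, "alt_frac_threshold": 0.05, **overrides})

    @classmethod
    def deep_profile(cls, **overrides) -> "HMMConfig":
        return cls(**{"min_segment_bins": 20, "alt_frac_threshold": 0.01, **overrides})


@dataclass
class TumorFractionSolution:
    """One fitted restart (or the selected solution) of the mixture HMM."""

    tumor_fraction: float
    tumor_ploidy: float
    subclonal_prevalence: float
    variance: float
    log_likelihood: float
    state_path: np.ndarray  # per-bin state index, -1 at masked bins
    segments: pd.DataFrame
    frac_genome_altered: float
    frac_genome_subclonal: float
    subclone_fractions: dict[str, float]
    mean_tumor_cn: float
    converged: bool
    n_iter: int
    alpha_init: float
    ploidy_init: float
    detected: bool | None = None
    flags: tuple[str, ...] = ()
    ll_history: tuple[float, ...] = ()


# ---------------------------------------------------------------------------
# state space and parameterization


def build_state_space(config: HMMConfig) -> list[HMMState]:
    """Clonal states for CN 0..max_cn, then one subclonal state per entry
    of the subclonal CN set; deterministic ordering."""
    states = [HMMState(label=f"CN{c}", copy_number=c) for c in range(config.max_cn + 1)]
    for c in sorted(config.subclonal_cn):
        states.append(HMMState(label=f"CN{c}s", copy_number=c, subclonal=True))
    return states


def expected_log_ratio(
    state: HMMState,
    alpha: float,
    s: float,
    phi_t: float,
    phi_n: float = 2.0,
) -> float:
    """Expected log2 ratio of one state under the two-population mixture."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    if phi_t <= 0 or phi_n <= 0:
        raise ValueError("ploidies must be positive")
    c_eff = s * state.copy_number + (1.0 - s) * phi_n if state.subclonal else float(state.copy_number)
    num = alpha * c_eff + (1.0 - alpha) * phi_n
    den = alpha * phi_t + (1.0 - alpha) * phi_n
    return float(np.log2(max(num / den, LOG_RATIO_FLOOR)))


def state_means(
    states: Sequence[HMMState],
    alpha: float,
    s: float,
    phi_t: float,
    phi_n: float = 2.0,
) -> np.ndarray:
    cn = np.array([st.copy_number for st in states], dtype=float)
    sub = np.array([st.subclonal for st in states])
    c_eff = np.where(sub, s * cn + (1.0 - s) * phi_n, cn)
    num = alpha * c_eff + (1.0 - alpha) * phi_n
    den = alpha * phi_t + (1.0 - alpha) * phi_n
    return np.log2(np.maximum(num / den, LOG_RATIO_FLOOR))


def transition_matrix(n_states: int, txn_e: float) -> np.ndarray:
    """Sticky uniform transition matrix; rows sum to exactly 1."""
    if n_states < 2:
        raise ValueError("need at least 2 states")
    off = (1.0 - txn_e) / (n_states - 1)
    A = np.full((n_states, n_states), off)
    np.fill_diagonal(A, txn_e)
    for i in range(n_states):
        j = n_states - 1 if i != n_states - 1 else n_states - 2
        A[i, j] += 1.0 - A[i].sum()
    return A


# ---------------------------------------------------------------------------
# emissions


def _t_logpdf(x: np.ndarray, loc: np.ndarray, scale: float, df: float) -> np.ndarray:
    z = (x - loc) / scale
    c = gammaln((df + 1.0) / 2.0) - gammaln(df / 2.0) - 0.5 * np.log(df * np.pi)
    return c - np.log(scale) - 0.5 * (df + 1.0) * np.log1p(z * z / df)


def _emission_logprob(
    x: np.ndarray, means: np.ndarray, variance: float, df: float
) -> np.ndarray:
    return _t_logpdf(x[:, None], means[None, :], float(np.sqrt(variance)), df)


def _chains(track: BinTrack) -> list[np.ndarray]:
    """Indices of unmasked bins per chromosome (chains restart at
    chromosome boundaries; masked bins are skipped within a chain)."""
    out = []
    for _, sl in track.grid.chrom_slices():
        idx = np.flatnonzero(track.unmasked[sl]) + sl.start
        if idx.size:
            out.append(idx)
    return out


def _check_track(track: BinTrack) -> None:
    vals = track.values[track.unmasked]
    if vals.size < 2:
        raise ValueError("track has fewer than 2 unmasked bins")
    if not np.all(np.isfinite(vals)):
        raise ValueError("track not sanitized")


# ---------------------------------------------------------------------------
# forward-backward / Viterbi


def _fb_chain(
    logB: np.ndarray, A: np.ndarray, pi: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Scaled forward-backward for one chain.

    Returns (posterior, expected transition counts, log-likelihood).
    """
    n, k = logB.shape
    shift = logB.max(axis=1)
    B = np.exp(logB - shift[:, None])
    if pi is None:
        pi = np.full(k, 1.0 / k)

    fwd = np.empty((n, k))
    c = np.empty(n)
    f = pi * B[0]
    c[0] = f.sum()
    fwd[0] = f / c[0]
    for t in range(1, n):
        f = (fwd[t - 1] @ A) * B[t]
        c[t] = f.sum()
        fwd[t] = f / c[t]

    bwd = np.empty((n, k))
    bwd[-1] = 1.0
    for t in range(n - 2, -1, -1):
        bwd[t] = (A @ (B[t + 1] * bwd[t + 1])) / c[t + 1]

    gamma = fwd * bwd
    gamma /= gamma.sum(axis=1, keepdims=True)

    xi = np.zeros((k, k))
    for t in range(n - 1):
        xi += np.outer(fwd[t], B[t + 1] * bwd[t + 1] / c[t + 1]) * A
    ll = float(np.log(c).sum() + shift.sum())
    return gamma, xi, ll


def forward_backward(
    track: BinTrack,
    states: Sequence[HMMState],
    alpha: float,
    phi_t: float,
    variance: float,
    config: HMMConfig,
    s: float = 0.5,
    trans: np.ndarray | None = None,
    pi: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Posterior state probabilities (NaN rows at masked bins) and total
    log-likelihood, summed over per-chromosome chains.

    The default initial distribution is uniform over states.
    """
    _check_track(track)
    if variance <= 0:
        raise ValueError("variance must be positive")
    k = len(states)
    if trans is not None:
        A = trans
    else:
        A = np.ones((1, 1)) if k == 1 else transition_matrix(k, config.txn_e)
    means = state_means(states, alpha, s, phi_t, config.normal_ploidy)
    gamma_full = np.full((track.grid.n_bins, k), np.nan)
    total_ll = 0.0
    for idx in _chains(track):
        logB = _emission_logprob(track.values[idx], means, variance, config.t_df)
        gamma, _, ll = _fb_chain(logB, A, pi)
        gamma_full[idx] = gamma
        total_ll += ll
    return gamma_full, total_ll


def viterbi(
    track: BinTrack,
    states: Sequence[HMMState],
    alpha: float,
    phi_t: float,
    variance: float,
    config: HMMConfig,
    s: float = 0.5,
    trans: np.ndarray | None = None,
    pi: np.ndarray | None = None,
) -> np.ndarray:
    """Most probable state path; ties break toward the lower state index.
    Masked bins carry -1."""
    _check_track(track)
    k = len(states)
    if trans is not None:
        A = trans
    else:
        A = np.ones((1, 1)) if k == 1 else transition_matrix(k, config.txn_e)
    logA = np.log(A)
    means = state_means(states, alpha, s, phi_t, config.normal_ploidy)
    log_pi = np.log(pi) if pi is not None else np.full(k, -np.log(k))
    path_full = np.full(track.grid.n_bins, -1, dtype=np.int64)
    for idx in _chains(track):
        logB = _emission_logprob(track.values[idx], means, variance, config.t_df)
        n = idx.size
        delta = log_pi + logB[0]
        back = np.zeros((n, k), dtype=np.int64)
        for t in range(1, n):
            scores = delta[:, None] + logA
            back[t] = scores.argmax(axis=0)  # first max -> lowest index
            delta = scores[back[t], np.arange(k)] + logB[t]
        path = np.empty(n, dtype=np.int64)
        path[-1] = int(delta.argmax())
        for t in range(n - 2, -1, -1):
            path[t] = back[t + 1, path[t + 1]]
        path_full[idx] = path
    return path_full


# ---------------------------------------------------------------------------
# EM


def _segments_from_path(
    track: BinTrack, path: np.ndarray, states: Sequence[HMMState]
) -> pd.DataFrame:
    grid = track.grid
    idx = np.flatnonzero(path >= 0)
    rows = []
    if idx.size:
        sub_path = path[idx]
        sub_chrom = grid.bin_chrom[idx]
        for a, b in _runs(sub_path, sub_chrom):
            sel = idx[a:b]
            st = states[int(sub_path[a])]
            rows.append(
                {
                    "chrom": grid.chrom_names[grid.bin_chrom[sel[0]]],
                    "start": int(grid.bin_start[sel[0]]),
                    "end": int(grid.bin_end[sel[-1]]),
                    "n_bins": len(sel),
                    "mean_log2": float(np.mean(track.values[sel])),
                    "copy_number": st.copy_number,
                    "state_label": st.label,
                    "subclonal": st.subclonal,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "n_bins", "mean_log2",
            "copy_number", "state_label", "subclonal",
        ],
    )


def em_fit(
    track: BinTrack,
    config: HMMConfig,
    alpha_init: float,
    ploidy_init: float,
) -> TumorFractionSolution:
    """Fit one restart by EM.

    The E-step runs forward-backward; the M-step does coordinate ascent:
    bounded scalar maximization of the expected log-likelihood for alpha,
    ploidy and the shared subclonal prevalence, a closed-form
    posterior-weighted update of the shared Student's-t variance, and a
    pseudo-count-smoothed transition update (prior mass = txn_strength
    times the sticky prior matrix).  Ploidy is softly anchored to its
    restart value by a Gaussian prior whose log-density is part of the
    reported (penalized) log-likelihood.  Non-convergence is reported via
    the ``converged`` flag, not an exception.
    """
    _check_track(track)
    states = build_state_space(config)
    k = len(states)
    has_sub = any(st.subclonal for st in states)
    chains = _chains(track)
    xs = [track.values[idx] for idx in chains]
    x_all = np.concatenate(xs)

    alpha = float(np.clip(alpha_init, *config.alpha_bounds))
    phi = float(np.clip(ploidy_init, *config.ploidy_bounds))
    s = 0.5
    variance = max(float(np.var(x_all)), 1e-6)
    prior = transition_matrix(k, config.txn_e)
    A = prior.copy()
    df = config.t_df
    phi_n = config.normal_ploidy
    pi = np.array(
        [
            config.neutral_kappa if (st.copy_number == 2 and not st.subclonal) else 1.0
            for st in states
        ]
    )
    pi /= pi.sum()

    def phi_log_prior(p: float) -> float:
        sd = config.ploidy_prior_sd
        if not sd or sd <= 0:
            return 0.0
        return float(
            -0.5 * ((p - ploidy_init) / sd) ** 2 - np.log(sd * np.sqrt(2 * np.pi))
        )

    def e_step():
        gamma_parts, xi_sum, ll = [], np.zeros((k, k)), 0.0
        means = state_means(states, alpha, s, phi, phi_n)
        for x in xs:
            logB = _emission_logprob(x, means, variance, df)
            gamma, xi, ll_c = _fb_chain(logB, A, pi)
            gamma_parts.append(gamma)
            xi_sum += xi
            ll += ll_c
        return np.vstack(gamma_parts), xi_sum, ll

    def neg_q(gamma, a, sv, p):
        means = state_means(states, a, sv, p, phi_n)
        return -float(
            (gamma * _emission_logprob(x_all, means, variance, df)).sum()
        )

    ll_history: list[float] = []
    converged = False
    prev_ll = -np.inf
    n_iter = 0
    for n_iter in range(1, config.max_iter + 1):
        gamma, xi_sum, ll = e_step()
        ll = ll + phi_log_prior(phi)
        ll_history.append(ll)
        if np.isfinite(prev_ll) and abs(ll - prev_ll) < config.em_tol * abs(prev_ll):
            converged = True
            break
        prev_ll = ll

        opts = {"xatol": config.scalar_tol}
        alpha = float(
            minimize_scalar(
                lambda a: neg_q(gamma, a, s, phi),
                bounds=config.alpha_bounds, method="bounded", options=opts,
            ).x
        )
        phi = float(
            minimize_scalar(
                lambda p: neg_q(gamma, alpha, s, p) - phi_log_prior(p),
                bounds=config.ploidy_bounds, method="bounded", options=opts,
            ).x
        )
        if has_sub:
            s = float(
                minimize_scalar(
                    lambda sv: neg_q(gamma, alpha, sv, phi),
                    bounds=config.s_bounds, method="bounded", options=opts,
                ).x
            )
        # Student's-t scale update with latent-scale weights (ECM step).
        means = state_means(states, alpha, s, phi, phi_n)
        resid2 = (x_all[:, None] - means[None, :]) ** 2
        u = (df + 1.0) / (df + resid2 / variance)
        variance = max(float((gamma * u * resid2).sum() / gamma.sum()), 1e-8)
        A = xi_sum + config.txn_strength * prior
        A /= A.sum(axis=1, keepdims=True)

    path = viterbi(track, states, alpha, phi, variance, config, s=s, trans=A, pi=pi)
    segments = _segments_from_path(track, path, states)
    on = path >= 0
    n_on = int(on.sum())
    altered = np.array([st.altered for st in states])
    sub = np.array([st.subclonal for st in states])
    frac_alt = float(altered[path[on]].sum() / n_on) if n_on else 0.0
    frac_sub = float(sub[path[on]].sum() / n_on) if n_on else 0.0
    sub_fracs = {
        st.label: float((path[on] == i).sum() / n_on) if n_on else 0.0
        for i, st in enumerate(states)
        if st.subclonal
    }
    cn = np.array([st.copy_number for st in states], dtype=float)
    c_eff = np.where(
        [st.subclonal for st in states], s * cn + (1.0 - s) * phi_n, cn
    )
    mean_cn = float(c_eff[path[on]].mean()) if n_on else phi_n
    return TumorFractionSolution(
        tumor_fraction=alpha,
        tumor_ploidy=phi,
        subclonal_prevalence=s,
        variance=variance,
        log_likelihood=ll_history[-1],
        state_path=path,
        segments=segments,
        frac_genome_altered=frac_alt,
        frac_genome_subclonal=frac_sub,
        subclone_fractions=sub_fracs,
        mean_tumor_cn=mean_cn,
        converged=converged,
        n_iter=n_iter,
        alpha_init=alpha_init,
        ploidy_init=ploidy_init,
        ll_history=tuple(ll_history),
    )


# ---------------------------------------------------------------------------
# solution selection / detection


def select_solution(
    solutions: Sequence[TumorFractionSolution],
    config: HMMConfig | None = None,
) -> TumorFractionSolution:
    """Filter by subclonal-genome rules, then return the highest
    log-likelihood survivor (flagged fallback if none survive)."""
    if not solutions:
        raise ValueError("no solutions")
    config = config or HMMConfig()
    admissible = [
        sol
        for sol in solutions
        if sol.frac_genome_subclonal < config.max_subclonal_genome_frac
        and all(f < config.max_subclone_genome_frac for f in sol.subclone_fractions.values())
        and abs(sol.tumor_ploidy - sol.mean_tumor_cn) <= config.max_ploidy_discordance
    ]
    if admissible:
        ll_max = max(sol.log_likelihood for sol in admissible)
        near_ties = [
            sol
            for sol in admissible
            if sol.log_likelihood >= ll_max - config.ll_tie_window
        ]
        return min(
            near_ties,
            key=lambda sol: (sol.frac_genome_altered, -sol.log_likelihood),
        )
    best = max(solutions, key=lambda sol: sol.log_likelihood)
    return replace(best, flags=best.flags + ("no admissible solution",))


def detection_gate(
    solution: TumorFractionSolution, config: HMMConfig
) -> TumorFractionSolution:
    """Zero the reported tumor fraction when the called profile lacks a
    credible alteration footprint."""
    seg = solution.segments
    altered = seg[(seg["copy_number"] != 2) | seg["subclonal"]] if len(seg) else seg
    longest = int(altered["n_bins"].max()) if len(altered) else 0
    if (
        solution.frac_genome_altered < config.alt_frac_threshold
        or longest < config.min_segment_bins
    ):
        return replace(
            solution,
            tumor_fraction=0.0,
            detected=False,
            flags=solution.flags + ("not detected",),
        )
    return replace(solution, detected=True)


def fit_tumor_fraction(
    track: BinTrack, config: HMMConfig
) -> tuple[TumorFractionSolution, list[TumorFractionSolution]]:
    """Run the full restart grid, select the optimal solution and apply
    the detection gate.  Returns (selected, all restart solutions)."""
    solutions = [
        em_fit(track, config, alpha_init=1.0 - nf, ploidy_init=pl)
        for nf in config.normal_restarts
        for pl in config.ploidy_restarts
    ]
    best = select_solution(solutions, config)
    return detection_gate(best, config), solutions


def solution_summary(
    solution: TumorFractionSolution, sample: str
) -> dict[str, object]:
    return {
        "sample": sample,
        "tumor_fraction": solution.tumor_fraction,
        "ploidy": solution.tumor_ploidy,
        "log_likelihood": solution.log_likelihood,
        "n_segments": len(solution.segments),
        "frac_genome_altered": solution.frac_genome_altered,
        "frac_subclonal": solution.frac_genome_subclonal,
        "converged": solution.converged,
        "detected": bool(solution.detected),
    }
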