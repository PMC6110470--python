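"""3-state HMM segmentation of normalized read depth.

States are diploid (DIP), deletion (DEL) and duplication (DUP), with Gaussian
emissions on the normalized z-scores (means 0 / del_mean / dup_mean, common
sd). Transitions depend on the genomic distance d between adjacent target
midpoints: with attrition factor f = exp(-d / D), a CNV state persists with
probability f and otherwise reverts to the quasi-stationary distribution
(1 - 2p, p, p), so the CNV->diploid probability grows as 1 - exp(-d / D).
Adjacent targets on different chromosomes are treated as infinitely distant
(f = 0), which resets the chain.

Viterbi supplies the most probable state path; maximal non-diploid runs
become calls. Forward-backward supplies Q_SOME, the phred-scaled posterior
probability that at least one target inside a called segment occupies the
call's CNV state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calls import DEL, DUP, CnvCall

__all__ = [
    "HmmParams",
    "viterbi_segment",
    "viterbi_paths",
    "forward_backward",
    "score_call",
    "call_cohort",
    "STATE_DIP",
    "STATE_DEL",
    "STATE_DUP",
]

STATE_DIP, STATE_DEL, STATE_DUP = 0, 1, 2
_STATE_TYPE = {STATE_DEL: DEL, STATE_DUP: DUP}


@dataclass(frozen=True)
class HmmParams:
    """Transition/emission parameters of the depth HMM.

    p_cnv: probability of entering a CNV state between adjacent targets.
    mean_cnv_attrition_bp: distance scale D (bp) of CNV persistence; the
        CNV->diploid transition probability grows as 1 - exp(-d / D).
    del_mean / dup_mean: emission means (z units) of the DEL / DUP states.
    emission_sd: common emission standard deviation.
    """

    p_cnv: float = 1e-8
    mean_cnv_attrition_bp: float = 70_000.0
    del_mean: float = -3.0
    dup_mean: float = 3.0
    emission_sd: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.p_cnv < 0.5:
            raise ValueError("p_cnv must lie in (0, 0.5)")
        if self.mean_cnv_attrition_bp <= 0:
            raise ValueError("attrition distance must be positive")
        if self.emission_sd <= 0:
            raise ValueError("emission_sd must be positive")

    @property
    def initial(self) -> np.ndarray:
        p = self.p_cnv
        return np.array([1.0 - 2.0 * p, p, p])

    def transition(self, distance_bp: float) -> np.ndarray:
        """Row-stochastic 3x3 transition matrix for inter-target distance d."""
        p = self.p_cnv
        pi = np.array([1.0 - 2.0 * p, p, p])
        f = math.exp(-distance_bp / self.mean_cnv_attrition_bp) if np.isfinite(distance_bp) else 0.0
        t = np.empty((3, 3))
        t[STATE_DIP] = pi
        for s in (STATE_DEL, STATE_DUP):
            t[s] = (1.0 - f) * pi
            t[s, s] += f
        return t

    def emission_means(self) -> np.ndarray:
        return np.array([0.0, self.del_mean, self.dup_mean])


def _target_midpoints(targets: pd.DataFrame) -> np.ndarray:
    return (targets["start"].to_numpy() + targets["end"].to_numpy()) / 2.0


def _adjacent_distances(targets: pd.DataFrame) -> np.ndarray:
    """Midpoint distance between consecutive targets; inf across chromosomes."""
    mid = _target_midpoints(targets)
    d = np.abs(np.diff(mid))
    chrom = targets["chrom"].to_numpy()
    d[chrom[1:] != chrom[:-1]] = np.inf
    return d


def _transition_stack(targets: pd.DataFrame, params: HmmParams) -> np.ndarray:
    d = _adjacent_distances(targets)
    return np.stack([params.transition(di) for di in d]) if len(d) else np.empty((0, 3, 3))


def _log_emissions(z: np.ndarray, params: HmmParams) -> np.ndarray:
    """log N(z | mu_s, sd) for each state; shape (..., T, 3)."""
    mu = params.emission_means()
    sd = params.emission_sd
    zz = np.asarray(z, dtype=float)[..., None]
    return -0.5 * ((zz - mu) / sd) ** 2 - math.log(sd) - 0.5 * math.log(2.0 * math.pi)


def viterbi_paths(z: np.ndarray, targets: pd.DataFrame, params: HmmParams) -> np.ndarray:
    """Most probable state path per sample row; z shape (n_samples, T)."""
    z = np.atleast_2d(np.asarray(z, dtype=float))
    n, t_len = z.shape
    if t_len != len(targets):
        raise ValueError(f"z has {t_len} targets, matrix has {len(targets)}")
    if not np.isfinite(z).all():
        raise ValueError("z must be finite")
    log_e = _log_emissions(z, params)  # (n, T, 3)
    with np.errstate(divide="ignore"):
        log_trans = np.log(_transition_stack(targets, params))  # (T-1, 3, 3)
        log_init = np.log(params.initial)
    delta = log_init + log_e[:, 0]  # (n, 3)
    back = np.zeros((n, t_len, 3), dtype=np.int8)
    for t in range(1, t_len):
        cand = delta[:, :, None] + log_trans[t - 1]  # (n, from, to)
        # argmax over source state; lowest state index wins ties (DIP<DEL<DUP)
        best = cand.argmax(axis=1)
        back[:, t] = best
        delta = np.take_along_axis(cand, best[:, None, :], axis=1)[:, 0] + log_e[:, t]
    states = np.empty((n, t_len), dtype=np.int8)
    states[:, -1] = delta.argmax(axis=1)
    for t in range(t_len - 1, 0, -1):
        states[:, t - 1] = np.take_along_axis(back[:, t], states[:, t, None], axis=1)[:, 0]
    return states


def _runs_to_calls(
    states: np.ndarray, z_row: np.ndarray, targets: pd.DataFrame, sample: str
) -> list[CnvCall]:
    chrom = targets["chrom"].to_numpy()
    starts = targets["start"].to_numpy()
    ends = targets["end"].to_numpy()
    calls: list[CnvCall] = []
    t = 0
    t_len = len(states)
    while t < t_len:
        s = states[t]
        if s == STATE_DIP:
            t += 1
            continue
        u = t
        while u + 1 < t_len and states[u + 1] == s and chrom[u + 1] == chrom[t]:
            u += 1
        calls.append(
            CnvCall(
                sample=sample,
                chrom=str(chrom[t]),
                start=int(starts[t]),
                end=int(ends[u]),
                type=_STATE_TYPE[int(s)],
                n_targets=u - t + 1,
                z_mean=float(z_row[t : u + 1].mean()),
            )
        )
        t = u + 1
    return calls


def viterbi_segment(
    z_row: np.ndarray, targets: pd.DataFrame, params: HmmParams, sample: str = "sample"
) -> list[CnvCall]:
    """Segment one sample's z row into unscored DEL/DUP calls."""
    z_row = np.asarray(z_row, dtype=float)
    states = viterbi_paths(z_row[None, :], targets, params)[0]
    return _runs_to_calls(states, z_row, targets, sample)


def forward_backward(
    z: np.ndarray, targets: pd.DataFrame, params: HmmParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scaled forward/backward passes.

    Returns (alpha_hat, beta_hat, log_c) with shapes (n, T, 3), (n, T, 3) and
    (n, T); per-target posteriors are alpha_hat * beta_hat (rows sum to 1).
    Scaling keeps every quantity finite for arbitrarily long rows.
    """
    z = np.atleast_2d(np.asarray(z, dtype=float))
    n, t_len = z.shape
    if t_len != len(targets):
        raise ValueError(f"z has {t_len} targets, matrix has {len(targets)}")
    log_e = _log_emissions(z, params)
    emis = np.exp(log_e - log_e.max(axis=2, keepdims=True))
    # note: per-cell emission rescaling cancels in all posterior ratios and is
    # absorbed into the scale factors, so it never biases Q_SOME
    trans = _transition_stack(targets, params)  # (T-1, 3, 3)
    alpha = np.empty((n, t_len, 3))
    log_c = np.empty((n, t_len))
    a = params.initial * emis[:, 0]
    c = a.sum(axis=1)
    alpha[:, 0] = a / c[:, None]
    log_c[:, 0] = np.log(c)
    for t in range(1, t_len):
        a = np.einsum("ni,ij->nj", alpha[:, t - 1], trans[t - 1]) * emis[:, t]
        c = a.sum(axis=1)
        alpha[:, t] = a / c[:, None]
        log_c[:, t] = np.log(c)
    beta = np.empty((n, t_len, 3))
    beta[:, -1] = 1.0
    for t in range(t_len - 2, -1, -1):
        b = np.einsum("ij,nj->ni", trans[t], emis[:, t + 1] * beta[:, t + 1])
        beta[:, t] = b / np.exp(log_c[:, t + 1])[:, None]
    return alpha, beta, log_c


def posteriors(z: np.ndarray, targets: pd.DataFrame, params: HmmParams) -> np.ndarray:
    """Per-target state posteriors, shape (n, T, 3); rows sum to 1."""
    alpha, beta, _ = forward_backward(z, targets, params)
    return alpha * beta


def _segment_some_probability(
    alpha: np.ndarray,
    beta: np.ndarray,
    emis_like: np.ndarray,
    trans: np.ndarray,
    log_c: np.ndarray,
    t0: int,
    t1: int,
    state: int,
) -> np.ndarray:
    """P(>=1 target in [t0, t1] occupies `state` | data), per sample.

    Computed as 1 - P(state avoided on every target of the segment), via a
    forward recursion restricted to the complement states, run in the same
    scaled space as the unrestricted pass.
    """
    mask = np.ones(3)
    mask[state] = 0.0
    r = alpha[:, t0] * mask
    for t in range(t0 + 1, t1 + 1):
        r = np.einsum("ni,ij->nj", r, trans[t - 1]) * emis_like[:, t]
        r = r / np.exp(log_c[:, t])[:, None]
        r = r * mask
    p_none = (r * beta[:, t1]).sum(axis=1)
    return 1.0 - np.clip(p_none, 0.0, 1.0)


def _phred(p_some: float) -> int:
    p_none = 1.0 - p_some
    if p_none <= 0.0:
        return 99
    return min(99, int(round(-10.0 * math.log10(p_none))))


def score_call(
    z_row: np.ndarray, targets: pd.DataFrame, params: HmmParams, call: CnvCall
) -> CnvCall:
    """Attach Q_SOME (and recompute z_mean) to a call via forward-backward."""
    calls = score_calls(np.asarray(z_row, dtype=float)[None, :], targets, params, [(0, call)])
    return calls[0]


def score_calls(
    z: np.ndarray,
    targets: pd.DataFrame,
    params: HmmParams,
    indexed_calls: list[tuple[int, CnvCall]],
) -> list[CnvCall]:
    """Score many calls against a multi-sample z matrix.

    ``indexed_calls`` pairs each call with its row index in ``z``.
    """
    z = np.atleast_2d(np.asarray(z, dtype=float))
    alpha, beta, log_c = forward_backward(z, targets, params)
    raw = _log_emissions(z, params)
    emis_like = np.exp(raw - raw.max(axis=2, keepdims=True))
    trans = _transition_stack(targets, params)
    starts = targets["start"].to_numpy()
    ends = targets["end"].to_numpy()
    chrom = targets["chrom"].to_numpy()
    out: list[CnvCall] = []
    for row, call in indexed_calls:
        in_seg = (chrom == call.chrom) & (starts >= call.start) & (ends <= call.end)
        idx = np.flatnonzero(in_seg)
        if len(idx) == 0:
            raise ValueError(f"call {call.interval} covers no targets")
        state = STATE_DEL if call.type == DEL else STATE_DUP
        p_some = _segment_some_probability(
            alpha[row : row + 1],
            beta[row : row + 1],
            emis_like[row : row + 1],
            trans,
            log_c[row : row + 1],
            int(idx[0]),
            int(idx[-1]),
            state,
        )[0]
        z_mean = float(z[row, idx].mean())
        out.append(
            CnvCall(
                sample=call.sample,
                chrom=call.chrom,
                start=call.start,
                end=call.end,
                type=call.type,
                n_targets=len(idx),
                z_mean=z_mean,
                q_some=_phred(float(p_some)),
            )
        )
    return out


def call_cohort(samples: list[str], z: np.ndarray, targets: pd.DataFrame, params: HmmParams) -> list[CnvCall]:
    """Viterbi-segment and score every sample of a normalized matrix."""
    z = np.atleast_2d(np.asarray(z, dtype=float))
    states = viterbi_paths(z, targets, params)
    indexed: list[tuple[int, CnvCall]] = []
    for i, sample in enumerate(samples):
        for call in _runs_to_calls(states[i], z[i], targets, sample):
            indexed.append((i, call))
    if not indexed:
        return []
    return score_calls(z, targets, params, indexed)
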