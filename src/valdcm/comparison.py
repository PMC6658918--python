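"""Random-effects Bayesian model selection and Bayesian model averaging.

Model identity is treated as a random effect across subjects: the frequency
profile r over K options (models or families) carries a Dirichlet(alpha)
posterior updated variationally from the per-subject log evidences.
Reported quantities are the expected posterior probabilities alpha/sum(alpha)
and the exceedance probabilities P(r_k > r_j for all j != k), estimated by
seeded Monte-Carlo Dirichlet sampling.

Family-level comparison corrects for unequal family sizes: each subject's
family evidence is the log-sum-exp of its member-model evidences minus
log(family size), which implements a uniform prior over families with the
prior mass equalised inside each family — without it the 225-model
bidirectional family would win on size alone.

Bayesian model averaging weights each model's posterior parameter means by
the subject's posterior probability of that model (restricted to the chosen
family and renormalised); parameters absent from a model contribute zero,
so averaged estimates shrink with model uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma, logsumexp

from .inversion import InversionResult
from .modelspace import FAMILIES, FamilyPartition

__all__ = [
    "BMSResult",
    "BMAParameters",
    "rfx_bms",
    "family_bms",
    "bma",
    "exceedance_from_alpha",
]


@dataclass(frozen=True)
class BMSResult:
    """Dirichlet posterior over model (or family) frequencies."""

    alpha: np.ndarray
    expected_prob: np.ndarray
    exceedance_prob: np.ndarray
    level: str                       # 'models' | 'families'
    option_ids: tuple = ()
    subject_posteriors: np.ndarray | None = None
    n_samples: int = 0
    exceedance_mc_se: float = 0.0

    def winner(self):
        return self.option_ids[int(np.argmax(self.exceedance_prob))]


@dataclass(frozen=True)
class BMAParameters:
    """Model-averaged parameters per subject plus the group summary."""

    subject_values: pd.DataFrame     # rows = subjects, columns = parameter names
    weights: pd.DataFrame            # rows = subjects, columns = model ids
    family: str

    @property
    def group_mean(self) -> pd.Series:
        return self.subject_values.mean(axis=0)

    @property
    def group_sd(self) -> pd.Series:
        return self.subject_values.std(axis=0, ddof=1)


def exceedance_from_alpha(
    alpha: np.ndarray, n_samples: int = 100_000, seed: int = 0
) -> tuple[np.ndarray, float]:
    """Monte-Carlo exceedance probabilities of a Dirichlet(alpha) frequency.

    Returns the probability per option of being the most frequent, plus the
    worst-case Monte-Carlo standard error of those estimates.
    """
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=n_samples)
    winners = np.argmax(draws, axis=1)
    xp = np.bincount(winners, minlength=alpha.size) / n_samples
    mc_se = float(np.max(np.sqrt(xp * (1 - xp) / n_samples)))
    return xp, mc_se


def rfx_bms(
    log_evidence: np.ndarray,
    alpha0: float = 1.0,
    option_ids: tuple | None = None,
    level: str = "models",
    n_samples: int = 100_000,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 10_000,
) -> BMSResult:
    """Variational random-effects BMS over a subjects-by-options evidence matrix.

    Iterates the per-subject posterior over options,
    ``u_nk ∝ exp(logev_nk + psi(alpha_k) - psi(sum alpha))``, and the
    Dirichlet update ``alpha = alpha0 + sum_n u_n`` until the alpha change
    falls below ``tol``.
    """
    log_evidence = np.asarray(log_evidence, dtype=float)
    if log_evidence.ndim != 2 or log_evidence.shape[1] < 2:
        raise ValueError("need a subjects x K evidence matrix with K >= 2")
    if not np.all(np.isfinite(log_evidence)):
        raise ValueError("log evidences must be finite")
    N, K = log_evidence.shape
    option_ids = tuple(option_ids) if option_ids is not None else tuple(range(K))

    alpha = np.full(K, alpha0, dtype=float)
    u = np.zeros((N, K))
    for _ in range(max_iter):
        log_u = log_evidence + digamma(alpha) - digamma(alpha.sum())
        log_u -= logsumexp(log_u, axis=1, keepdims=True)
        u = np.exp(log_u)
        alpha_new = alpha0 + u.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new

    xp, mc_se = exceedance_from_alpha(alpha, n_samples=n_samples, seed=seed)
    return BMSResult(
        alpha=alpha,
        expected_prob=alpha / alpha.sum(),
        exceedance_prob=xp,
        level=level,
        option_ids=option_ids,
        subject_posteriors=u,
        n_samples=n_samples,
        exceedance_mc_se=mc_se,
    )


def family_evidence(
    log_evidence: np.ndarray,
    partition: FamilyPartition,
    model_ids: tuple[int, ...] | None = None,
) -> np.ndarray:
    """Per-subject family evidences with the family-size correction."""
    log_evidence = np.asarray(log_evidence, dtype=float)
    N, K = log_evidence.shape
    model_ids = tuple(model_ids) if model_ids is not None else tuple(sorted(partition.family_of_model))
    if len(model_ids) != K:
        raise ValueError(f"evidence matrix has {K} columns but {len(model_ids)} model ids given")
    fam_ev = np.empty((N, len(FAMILIES)))
    for f, family in enumerate(FAMILIES):
        members = [i for i, mid in enumerate(model_ids)
                   if partition.family_of_model[mid] == family]
        if not members:
            raise ValueError(f"family {family!r} has no member in the model set")
        fam_ev[:, f] = logsumexp(log_evidence[:, members], axis=1) - np.log(len(members))
    return fam_ev


def family_bms(
    log_evidence: np.ndarray,
    partition: FamilyPartition,
    model_ids: tuple[int, ...] | None = None,
    **kwargs,
) -> BMSResult:
    """Random-effects BMS at the family level (size-corrected evidences)."""
    fam_ev = family_evidence(log_evidence, partition, model_ids)
    return rfx_bms(fam_ev, option_ids=FAMILIES, level="families", **kwargs)


def bma(
    inversions: dict[str, dict[int, InversionResult]],
    bms: BMSResult,
    family: str,
    partition: FamilyPartition,
) -> BMAParameters:
    """Average parameters over the models of one family, per subject.

    ``inversions`` maps subject -> model_id -> result; ``bms`` must be a
    model-level result whose ``option_ids`` are model ids and whose
    ``subject_posteriors`` rows follow the order of ``inversions``.
    Parameters absent from a model enter the average as zero.
    """
    if bms.level != "models" or bms.subject_posteriors is None:
        raise ValueError("bma needs a model-level BMS result with subject posteriors")
    member_ids = [mid for mid in bms.option_ids if partition.family_of_model[mid] == family]
    if not member_ids:
        raise ValueError(f"family {family!r} has no members among the BMS options")

    subjects = list(inversions)
    missing = {
        sub: [mid for mid in member_ids if mid not in inversions[sub]]
        for sub in subjects
    }
    missing = {s: m for s, m in missing.items() if m}
    if missing:
        raise ValueError(f"missing inversions for family {family!r}: {missing}")

    all_names: list[str] = []
    for sub in subjects:
        for mid in member_ids:
            for name in inversions[sub][mid].layout.names:
                if name not in all_names:
                    all_names.append(name)

    col_of = {mid: bms.option_ids.index(mid) for mid in member_ids}
    values = np.zeros((len(subjects), len(all_names)))
    weights = np.zeros((len(subjects), len(member_ids)))
    for s, sub in enumerate(subjects):
        w = np.array([bms.subject_posteriors[s, col_of[mid]] for mid in member_ids])
        total = w.sum()
        w = w / total if total > 0 else np.full(len(member_ids), 1.0 / len(member_ids))
        weights[s] = w
        for mid, wm in zip(member_ids, w):
            for name, mean in inversions[sub][mid].named_means.items():
                values[s, all_names.index(name)] += wm * mean

    return BMAParameters(
        subject_values=pd.DataFrame(values, index=subjects, columns=all_names),
        weights=pd.DataFrame(weights, index=subjects, columns=member_ids),
        family=family,
    )
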