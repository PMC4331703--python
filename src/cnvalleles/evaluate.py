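"""Allele calling, concordance metrics, copy-number calls, trio checks.

Concordance between a predicted and a true allele set is scored per allele by
the best base-match ratio against the other set:

    precision = (1/K)   sum_k  max_l r_kl
    recall    = (1/K0)  sum_l  max_k r_kl

with ``r_kl`` the fraction of variable sites at which predicted allele k and
true allele l carry the same base.  Both are averages of per-allele maxima
(no one-to-one assignment), so duplicated predicted alleles can inflate
precision; the F-measure is their harmonic mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .inference import BASES, ModelParams, VariationalState
from .simulate import AlleleSet


@dataclass
class ConcordanceReport:
    precision: float
    recall: float
    f_measure: float
    r_matrix: np.ndarray  # (K_pred, K_true) match ratios


@dataclass
class CopyNumberCall:
    """Integer per-allele copy numbers for one sample."""

    theta_hat: np.ndarray
    total_copies: int
    cn: np.ndarray

    def __post_init__(self) -> None:
        self.cn = np.asarray(self.cn, dtype=np.int64)
        if self.cn.sum() != self.total_copies:
            raise ValueError("copy numbers must sum to total_copies")
        if (self.cn < 0).any():
            raise ValueError("negative copy number")


def call_alleles(params: ModelParams) -> AlleleSet:
    """Most likely base per (allele, site): argmax_b phi[k, x, b].

    Ties resolve to the alphabetically first base (A < C < G < T), which is
    the order in which bases are stored.
    """
    idx = np.argmax(params.phi, axis=2)  # first max wins ties
    seqs = tuple("".join(BASES[b] for b in row) for row in idx)
    return AlleleSet(seqs)


def match_ratio(pred: str, truth: str) -> float:
    """Fraction of positions at which two equal-length sequences agree."""
    if len(pred) != len(truth):
        raise ValueError(
            f"sequence lengths differ: {len(pred)} vs {len(truth)}"
        )
    return sum(a == b for a, b in zip(pred, truth)) / len(pred)


def concordance(pred: AlleleSet, truth: AlleleSet) -> ConcordanceReport:
    """Precision/recall/F of a predicted allele set against the truth."""
    if pred.n_sites != truth.n_sites:
        raise ValueError("predicted and true alleles must share site count")
    r = np.array([[match_ratio(p, t) for t in truth.sequences]
                  for p in pred.sequences])
    precision = float(r.max(axis=1).mean())
    recall = float(r.max(axis=0).mean())
    denom = precision + recall
    f = 2 * precision * recall / denom if denom > 0 else 0.0
    return ConcordanceReport(precision=precision, recall=recall,
                             f_measure=f, r_matrix=r)


def copy_numbers(state: VariationalState, sample: int,
                 total_copies: int) -> CopyNumberCall:
    """Integer copy numbers from the posterior-mean allele proportions.

    The posterior mean theta_hat = r_n / sum_k r_nk is scaled by the sample's
    total copy number (supplied by the caller — e.g. from overall depth) and
    rounded by largest remainder so the parts always sum to the total.
    """
    if total_copies < 1:
        raise ValueError("total_copies must be >= 1")
    theta = state.theta_hat[sample]
    ideal = theta * total_copies
    cn = np.floor(ideal).astype(np.int64)
    short = total_copies - int(cn.sum())
    order = np.argsort(-(ideal - np.floor(ideal)), kind="stable")
    cn[order[:short]] += 1
    return CopyNumberCall(theta_hat=theta, total_copies=total_copies, cn=cn)


def trio_consistency(child: CopyNumberCall, father: CopyNumberCall,
                     mother: CopyNumberCall) -> dict:
    """Heredity check: a child's copy number of each allele cannot exceed the
    sum of its parents' copy numbers of that allele."""
    k = len(child.cn)
    if len(father.cn) != k or len(mother.cn) != k:
        raise ValueError("trio calls must cover the same alleles")
    violations = [int(i) for i in
                  np.flatnonzero(child.cn > father.cn + mother.cn)]
    return {"consistent": not violations, "violations": violations}
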