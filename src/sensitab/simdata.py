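"""Synthetic pharmacogenomic data with known ground truth.

Generates the three kinds of input the pipeline consumes, each with its
truth recorded so every downstream stage is testable without external
cohorts:

* two-class (sensitive/resistant) expression matrices with a configurable
  number of informative genes, mean-shift effect size (in noise-sd units),
  class imbalance and an unlabeled pool drawn from the same mixture, plus
  an IC50 table constructed so the < 500 nM sensitivity rule reproduces
  the intended labels exactly;
* noisy four-parameter-logistic viability curves;
* drug-combination grids with a known injected Bliss excess.

Expression baselines are lognormal (positive, right-skewed, like real
expression measurements); class separation is a mean shift on the log
scale restricted to the informative genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import DEFAULT_IC50_THRESHOLD_NM, ExpressionMatrix, DrugResponseTable
from .synergy import CombinationGrid, DoseResponseCurve, four_pl

import pandas as pd

__all__ = [
    "SimulationTruth",
    "make_pharmacogenomic",
    "make_dose_response",
    "make_combination_grid",
]


@dataclass
class SimulationTruth:
    """Ground truth recorded exactly as used by a generator."""

    seed: int
    informative_gene_ids: list = field(default_factory=list)
    effect_size: float = 0.0
    noise_sd: float = 0.0
    class_proportions: dict = field(default_factory=dict)
    labels: dict = field(default_factory=dict)        # sample id -> intended label
    fourpl_params: dict = field(default_factory=dict)
    bliss_excess: float | None = None
    notes: list = field(default_factory=list)


def _truncated_lognormal(rng, median_nM, sigma_log, size, low=None, high=None):
    """Lognormal IC50 draws rejected onto one side of the threshold."""
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.lognormal(mean=np.log(median_nM), sigma=sigma_log, size=size)
        if low is not None:
            draw = draw[draw >= low]
        if high is not None:
            draw = draw[draw < high]
        take = min(draw.size, size - filled)
        out[filled : filled + take] = draw[:take]
        filled += take
    return out


def make_pharmacogenomic(
    n_sensitive: int = 140,
    n_resistant: int = 191,
    n_genes: int = 200,
    n_informative: int = 10,
    effect_size: float = 3.0,
    noise_sd: float = 1.0,
    n_unlabeled: int = 264,
    seed: int = 0,
    drug: str = "venetoclax",
    threshold_nM: float = DEFAULT_IC50_THRESHOLD_NM,
):
    """Simulate an annotated cohort, an IC50 table and an unlabeled pool.

    Log-expression for gene g is ``base_g + shift_g * y + N(0, noise_sd)``
    where ``shift_g = effect_size * noise_sd`` for the ``n_informative``
    informative genes and 0 otherwise; expression is the exponential of
    that (lognormal).  Sensitive IC50s are lognormal centred at 100 nM
    truncated below the threshold; resistant ones centred at 2000 nM
    truncated above it, so binarizing the IC50 table reproduces the
    intended labels with zero error.  The unlabeled pool is drawn from the
    same class mixture.

    Returns ``(annotated, responses, unlabeled, truth)``.
    """
    if n_informative > n_genes:
        raise ValueError("n_informative cannot exceed n_genes")
    if min(n_sensitive, n_resistant) < 1 or n_genes < 1:
        raise ValueError("all counts must be >= 1")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    if effect_size < 0:
        raise ValueError("effect_size must be non-negative")
    rng = np.random.default_rng(seed)
    gene_ids = [f"g{j:04d}" for j in range(n_genes)]
    informative = gene_ids[:n_informative]
    base = rng.normal(1.0, 0.5, size=n_genes)
    shift = np.zeros(n_genes)
    shift[:n_informative] = effect_size * noise_sd

    def draw_block(n, label):
        log_expr = base + shift * label + rng.normal(0.0, noise_sd, size=(n, n_genes))
        return np.exp(log_expr)

    n_ann = n_sensitive + n_resistant
    labels = np.concatenate([np.ones(n_sensitive, int), np.zeros(n_resistant, int)])
    perm = rng.permutation(n_ann)
    labels = labels[perm]
    values = np.empty((n_ann, n_genes))
    values[labels == 1] = draw_block(n_sensitive, 1)
    values[labels == 0] = draw_block(n_resistant, 0)
    sample_ids = [f"s{i:04d}" for i in range(n_ann)]
    annotated = ExpressionMatrix(sample_ids, gene_ids, values)

    ic50 = np.empty(n_ann)
    ic50[labels == 1] = _truncated_lognormal(rng, 100.0, 0.8, n_sensitive, high=threshold_nM)
    ic50[labels == 0] = _truncated_lognormal(rng, 2000.0, 0.8, n_resistant, low=threshold_nM)
    responses = DrugResponseTable(
        pd.DataFrame({"sample_id": sample_ids, "drug": drug, "ic50_nM": ic50})
    )

    p_sensitive = n_sensitive / n_ann
    unlab_labels = (rng.random(n_unlabeled) < p_sensitive).astype(int)
    unlab_values = np.empty((n_unlabeled, n_genes))
    if (unlab_labels == 1).any():
        unlab_values[unlab_labels == 1] = draw_block(int((unlab_labels == 1).sum()), 1)
    if (unlab_labels == 0).any():
        unlab_values[unlab_labels == 0] = draw_block(int((unlab_labels == 0).sum()), 0)
    unlabeled = ExpressionMatrix(
        [f"u{i:04d}" for i in range(n_unlabeled)], gene_ids, unlab_values
    )

    truth = SimulationTruth(
        seed=seed,
        informative_gene_ids=informative,
        effect_size=effect_size,
        noise_sd=noise_sd,
        class_proportions={"sensitive": p_sensitive, "resistant": 1 - p_sensitive},
        labels={**dict(zip(sample_ids, labels.tolist())),
                **dict(zip(unlabeled.sample_ids, unlab_labels.tolist()))},
    )
    return annotated, responses, unlabeled, truth


def make_dose_response(
    bottom: float = 0.0,
    top: float = 1.0,
    ec50_nM: float = 100.0,
    hill: float = 1.0,
    doses=None,
    n_replicates: int = 3,
    noise_sd: float = 0.05,
    seed: int = 0,
    drug: str = "volasertib",
):
    """Simulate replicated viability measurements from a 4PL truth.

    Viability = 1 - effect(dose) + Gaussian noise, clipped to [0, 1.5].
    Returns ``(curve, truth)``.
    """
    if doses is None:
        doses = np.geomspace(ec50_nM / 100, ec50_nM * 100, 8)
    doses = np.asarray(doses, dtype=float)
    if (doses <= 0).any():
        raise ValueError("doses must be positive")
    if len(np.unique(doses)) < 4:
        raise ValueError("need at least 4 distinct doses")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    effect = four_pl(doses, bottom, top, ec50_nM, hill)
    viability = 1.0 - effect[None, :] + rng.normal(0.0, noise_sd, size=(n_replicates, doses.size))
    viability = np.clip(viability, 0.0, 1.5)
    curve = DoseResponseCurve(concentrations=doses, viability=viability, drug=drug)
    truth = SimulationTruth(
        seed=seed,
        noise_sd=noise_sd,
        fourpl_params={"bottom": bottom, "top": top, "ec50_nM": ec50_nM, "hill": hill},
    )
    return curve, truth


def make_combination_grid(
    e1_vector,
    e2_vector,
    excess_delta: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Simulate an observed combination-effect matrix with known Bliss excess.

    observed[i, j] = clip(e1[i] + e2[j] - e1[i]*e2[j] + excess_delta
    + noise, 0, 1).  Cells the clip actually moved are noted in the truth.
    Returns ``(grid, truth)``.
    """
    e1 = np.asarray(e1_vector, dtype=float)
    e2 = np.asarray(e2_vector, dtype=float)
    for name, e in (("e1_vector", e1), ("e2_vector", e2)):
        if e.min() < 0 or e.max() > 1:
            raise ValueError(f"{name} effects must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    expected = e1[:, None] + e2[None, :] - e1[:, None] * e2[None, :]
    raw = expected + excess_delta + rng.normal(0.0, noise_sd, size=expected.shape)
    observed = np.clip(raw, 0.0, 1.0)
    truth = SimulationTruth(seed=seed, noise_sd=noise_sd, bliss_excess=excess_delta)
    if not np.allclose(raw, observed):
        truth.notes.append("observed effects clipped into [0, 1]")
    grid = CombinationGrid(effects_drug1=e1, effects_drug2=e2, observed_combined=observed)
    return grid, truth
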