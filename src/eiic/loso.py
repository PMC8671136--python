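"""Leave-one-site-out cross-validation (LOSO-CV) harness.

Each acquisition site is held out in turn as the test set; all remaining
sites form the modeling set.  The modeling set is split into five stratified
folds whose site-by-class composition tracks the overall proportions; each
fold serves once as the validation set for early stopping, yielding five
trained models per site.  At test time each model standardizes the held-out
features with its *own* training-fold statistics, the five classifier-head
outputs are averaged, and the mean score is rounded to the predicted label
(ties at exactly 0.5 go to class 1).

Per-site accuracy is compared against the 50% chance level with an exact
two-sided binomial test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .features import (
    FeatureVector,
    apply_standardizer,
    fit_standardizer,
    stack_features,
)
from .network import NetworkSpec, build_network, freeze_trunk
from .training import TrainConfig, train_prior, train_supervised, train_transfer

__all__ = [
    "LosoSplit",
    "EnsembleModel",
    "loso_splits",
    "stratified_five_folds",
    "fit_site_ensemble",
    "ensemble_predict",
    "binomial_test",
    "loso_report",
]

logger = logging.getLogger(__name__)

N_FOLDS = 5
ALPHA = 0.01


@dataclass
class LosoSplit:
    test_site: str
    test: list[FeatureVector]
    modeling: list[FeatureVector]


@dataclass
class EnsembleModel:
    """Five (model, standardizer) members, one per validation fold."""

    members: list  # list of (EiicModel-like, StandardizerStats)


def loso_splits(
    features: Sequence[FeatureVector],
    min_site_size: int = 2,
) -> list[LosoSplit]:
    """One split per eligible test site; small sites still join modeling sets."""
    sites = sorted({f.site_id for f in features})
    counts = {s: sum(1 for f in features if f.site_id == s) for s in sites}
    eligible = [s for s in sites if counts[s] >= min_site_size]
    if len(sites) < 2:
        raise ValueError("LOSO needs at least 2 sites")
    if not eligible:
        raise ValueError(f"no site has >= {min_site_size} subjects to serve as a test set")
    splits = []
    for site in eligible:
        test = [f for f in features if f.site_id == site]
        modeling = [f for f in features if f.site_id != site]
        splits.append(LosoSplit(test_site=site, test=test, modeling=modeling))
    return splits


def stratified_five_folds(
    modeling: Sequence[FeatureVector],
    rng: np.random.Generator,
    n_folds: int = N_FOLDS,
) -> np.ndarray:
    """Fold index per modeling subject, stratified by (site x class) cell.

    Within each cell the members are shuffled and dealt round-robin, with the
    starting fold rotating across cells so remainders spread evenly; every
    fold's site and class composition then tracks the overall proportions.
    """
    if len(modeling) < 2 * n_folds:
        raise ValueError(f"need at least {2 * n_folds} modeling subjects")
    labels = np.array([f.label for f in modeling])
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present in the modeling set")
    cells: dict[tuple[str, int], list[int]] = {}
    for idx, f in enumerate(modeling):
        cells.setdefault((f.site_id, f.label), []).append(idx)
    assignment = np.empty(len(modeling), dtype=int)
    dealt = 0
    for key in sorted(cells):
        members = np.array(cells[key])
        members = members[rng.permutation(len(members))]
        for k, idx in enumerate(members):
            assignment[idx] = (dealt + k) % n_folds
        dealt += len(members)
    return assignment


def fit_site_ensemble(
    modeling: Sequence[FeatureVector],
    net_spec: NetworkSpec,
    train_config: TrainConfig,
    seed: int = 0,
    ablation: bool = False,
) -> EnsembleModel:
    """Train the five-fold ensemble on one site's modeling set.

    For each fold: fit the standardizer on the four training folds, run
    contrastive prior learning with that fold as validation, freeze the
    trunk, and fit the classifier head by cross-entropy.  With
    ``ablation=True`` the contrastive phase and the freeze are skipped and
    the whole network is trained supervised (the no-prior baseline).
    """
    ss = np.random.SeedSequence(seed)
    fold_seed, *member_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(6)]
    folds = stratified_five_folds(modeling, np.random.default_rng(fold_seed))
    members = []
    for k in range(N_FOLDS):
        train = [f for f, fold in zip(modeling, folds) if fold != k]
        val = [f for f, fold in zip(modeling, folds) if fold == k]
        stats = fit_standardizer(train)
        train_s = apply_standardizer(stats, train)
        val_s = apply_standardizer(stats, val)
        member_seed = member_seeds[k]
        spec = NetworkSpec(
            input_dim=net_spec.input_dim,
            hidden_dims=net_spec.hidden_dims,
            c_main=net_spec.c_main,
            c_oc=net_spec.c_oc,
            seed=member_seed,
        )
        cfg_kwargs = {**train_config.__dict__, "seed": member_seed}
        cfg = TrainConfig(**cfg_kwargs)
        model = build_network(spec)
        try:
            if ablation:
                model, hist = train_supervised(model, train_s, val_s, cfg)
            else:
                model, hist = train_prior(model, train_s, val_s, cfg)
                logger.info(
                    "fold %d prior: best epoch %d (val %.4f)%s",
                    k,
                    hist.best_epoch,
                    hist.val_loss[hist.best_epoch],
                    " [early stop]" if hist.stopped_early else "",
                )
                freeze_trunk(model)
                model, hist = train_transfer(model, train_s, val_s, cfg)
            logger.info(
                "fold %d final: best epoch %d (val %.4f)", k, hist.best_epoch,
                hist.val_loss[hist.best_epoch],
            )
        except Exception as exc:
            raise RuntimeError(f"training failed in fold {k}: {exc}") from exc
        members.append((model, stats))
    return EnsembleModel(members=members)


def ensemble_predict(
    ensemble: EnsembleModel,
    test: Sequence[FeatureVector],
) -> tuple[np.ndarray, np.ndarray]:
    """Average the five classifier outputs; round the mean score to a label.

    Returns ``(mean_scores, labels)`` where ``mean_scores`` is n x 2.  A mean
    class-1 score of exactly 0.5 predicts class 1 (documented tie-break).
    """
    if len(test) == 0:
        raise ValueError("empty test set")
    x, _, _, _ = stack_features(test)
    scores = []
    for model, stats in ensemble.members:
        scores.append(model.forward(stats.transform(x), "classifier", training=False))
    mean_scores = np.mean(scores, axis=0)
    labels = (mean_scores[:, 1] >= 0.5).astype(int)
    return mean_scores, labels


def binomial_test(k: int, n: int, p0: float = 0.5) -> float:
    """Exact two-sided binomial p-value for k successes out of n."""
    if n < 1 or not 0 <= k <= n:
        raise ValueError(f"invalid binomial counts k={k}, n={n}")
    return float(sps.binomtest(int(k), int(n), p0, alternative="two-sided").pvalue)


def loso_report(
    features: Sequence[FeatureVector],
    net_spec: NetworkSpec,
    train_config: TrainConfig,
    seed: int = 0,
    min_site_size: int = 2,
    ablation: bool = False,
) -> pd.DataFrame:
    """Run the full LOSO-CV pipeline and tabulate per-site performance.

    Returns a DataFrame with columns ``site, n, n_correct, accuracy,
    p_value, significant_0.01``, deterministic for a fixed seed.
    """
    splits = loso_splits(features, min_site_size=min_site_size)
    ss = np.random.SeedSequence(seed)
    site_seeds = {
        s.test_site: int(c.generate_state(1)[0] % 2**31)
        for s, c in zip(splits, ss.spawn(len(splits)))
    }
    rows = []
    for split in splits:
        test_ids = {f.subject_id for f in split.test}
        modeling_ids = {f.subject_id for f in split.modeling}
        assert not test_ids & modeling_ids, "leakage: test subjects in modeling set"
        ensemble = fit_site_ensemble(
            split.modeling,
            net_spec,
            train_config,
            seed=site_seeds[split.test_site],
            ablation=ablation,
        )
        _, pred = ensemble_predict(ensemble, split.test)
        truth = np.array([f.label for f in split.test])
        n_correct = int((pred == truth).sum())
        n = len(split.test)
        p = binomial_test(n_correct, n)
        rows.append(
            {
                "site": split.test_site,
                "n": n,
                "n_correct": n_correct,
                "accuracy": n_correct / n,
                "p_value": p,
                "significant_0.01": p < ALPHA,
            }
        )
        logger.info(
            "site %s: accuracy %.3f (%d/%d), p=%.4g",
            split.test_site, n_correct / n, n_correct, n, p,
        )
    return pd.DataFrame(rows)
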