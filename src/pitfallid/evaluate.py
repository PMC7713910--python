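"""Metrics and the four evaluation protocols.

Five metrics (top-1 and top-3 accuracy, macro-averaged precision, recall and
F1) are computed under:

* the **hierarchical** protocol — one species-level model per repeat, its
  ranked predictions lifted through the taxonomy and re-scored at every rank;
* the **single-level** protocol — a fresh model per rank trained on labels
  relabeled at that rank;
* the **local-pool** protocol — species predictions reranked within each
  collection site's known species pool;
* the **novel-species** protocol — rare species absent from training scored
  at the ranks where they share a clade with at least one training species.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import precision_recall_fscore_support

from .classify import ModelSpec, PredictionMatrix, train
from .manifest import feature_names
from .taxonomy import TaxonomyTable

METRICS = ("top1", "top3", "precision", "recall", "f1")


class EvaluateError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Core metrics


def topk_accuracy(preds: PredictionMatrix, truth, k: int = 1) -> float:
    """Fraction of rows whose true label is among the k top-ranked classes."""
    truth = np.asarray(truth, dtype=object)
    if len(truth) != preds.proba.shape[0]:
        raise EvaluateError("truth length does not match prediction rows")
    if k < 1:
        raise EvaluateError("k must be >= 1")
    n_classes = len(preds.classes)
    if k > n_classes:
        warnings.warn(
            f"k={k} exceeds the {n_classes} classes; clamping", stacklevel=2
        )
        k = n_classes
    top = preds.top_labels(k)
    hits = [t in row for t, row in zip(truth, top)]
    return float(np.mean(hits))


def macro_prf(
    pred_labels, truth, classes=None
) -> tuple[float, float, float]:
    """Macro-averaged precision, recall and F1 over ``classes``.

    ``classes`` defaults to the union of labels present in truth or
    predictions.  A class never predicted has precision 0; a class whose F1
    denominator is 0 has F1 = 0 (unweighted averaging throughout).
    """
    pred_labels = np.asarray(pred_labels, dtype=object)
    truth = np.asarray(truth, dtype=object)
    if len(pred_labels) != len(truth):
        raise EvaluateError("prediction/truth length mismatch")
    if classes is None:
        classes = sorted(set(truth) | set(pred_labels))
    p, r, f, _ = precision_recall_fscore_support(
        truth, pred_labels, labels=list(classes), average="macro", zero_division=0
    )
    return float(p), float(r), float(f)


def lifted_rankings(
    preds: PredictionMatrix, tax: TaxonomyTable, rank: str
) -> list[list[str]]:
    """Per-row ranked labels at ``rank``: lift the species ranking and
    collapse duplicate lifted labels, keeping first (best) occurrence."""
    lifted_classes = [tax.ancestor(str(c), rank) for c in preds.classes]
    rankings = preds.ranking()
    out = []
    for row in rankings:
        seen: list[str] = []
        for idx in row:
            lab = lifted_classes[idx]
            if lab not in seen:
                seen.append(lab)
        out.append(seen)
    return out


def _rank_metrics(
    preds: PredictionMatrix, truth, tax: TaxonomyTable, rank: str
) -> dict[str, float]:
    truth_r = tax.lift(list(truth), rank)
    ranked = lifted_rankings(preds, tax, rank)
    top1_labels = [r[0] for r in ranked]
    top1 = float(np.mean([t == r[0] for t, r in zip(truth_r, ranked)]))
    top3 = float(np.mean([t in r[:3] for t, r in zip(truth_r, ranked)]))
    p, r, f = macro_prf(top1_labels, truth_r)
    return {"top1": top1, "top3": top3, "precision": p, "recall": r, "f1": f}


def hierarchical_evaluate(
    preds: PredictionMatrix, truth, tax: TaxonomyTable, ranks=None
) -> pd.DataFrame:
    """All five metrics at every rank from one species-level prediction matrix.

    Lifting can only merge distinct wrong species into the right higher
    taxon, so top-1 accuracy is non-decreasing from species upward.
    """
    ranks = list(ranks or tax.ranks)
    rows = {rank: _rank_metrics(preds, truth, tax, rank) for rank in ranks}
    return pd.DataFrame.from_dict(rows, orient="index")[list(METRICS)]


def single_level_evaluate(
    spec: ModelSpec,
    splits,
    tax: TaxonomyTable,
    rank: str,
    fixed_params: list | None = None,
) -> pd.DataFrame:
    """Train fresh models on labels relabeled at ``rank``; score at that rank only.

    ``fixed_params`` (one per split) bypasses grid tuning with an already
    chosen hyperparameter, e.g. the one selected at species level.
    Returns one row per repeat; a rank with a single class yields trivially
    perfect metrics and is flagged in the ``degenerate`` column.
    """
    if rank not in tax.ranks:
        raise EvaluateError(f"unknown rank {rank!r}")
    feats = feature_names()
    rows = []
    for i, split in enumerate(splits):
        y_tr = np.asarray(tax.lift(list(split.train["species"]), rank), dtype=object)
        y_te = np.asarray(tax.lift(list(split.test["species"]), rank), dtype=object)
        X_tr = split.train[feats].to_numpy(float)
        X_te = split.test[feats].to_numpy(float)
        degenerate = len(set(y_tr)) < 2
        if degenerate:
            metrics = {m: 1.0 for m in METRICS}
        else:
            use_spec = spec
            if fixed_params is not None and spec.grid is not None:
                use_spec = ModelSpec(
                    algorithm=spec.algorithm,
                    grid=(int(fixed_params[i]),),
                    tuning_mode="paper-fidelity",
                    seed=spec.seed,
                    rf_trees=spec.rf_trees,
                    ann_max_iter=spec.ann_max_iter,
                )
            model = train(
                use_spec,
                X_tr,
                y_tr,
                eval_X=X_te if use_spec.tuning_mode == "paper-fidelity" else None,
                eval_y=y_te if use_spec.tuning_mode == "paper-fidelity" else None,
            )
            pm = model.prediction_matrix(X_te)
            top1_labels = pm.top_labels(1)[:, 0]
            p, r, f = macro_prf(top1_labels, y_te)
            metrics = {
                "top1": topk_accuracy(pm, y_te, 1),
                "top3": topk_accuracy(pm, y_te, min(3, len(pm.classes))),
                "precision": p,
                "recall": r,
                "f1": f,
            }
        metrics["repeat"] = split.repeat_index
        metrics["degenerate"] = degenerate
        rows.append(metrics)
    return pd.DataFrame(rows)[["repeat", *METRICS, "degenerate"]]


# ---------------------------------------------------------------------------
# Local species pools


@dataclass
class LocalResult:
    """Outcome of local-pool reranking for one repeat."""

    filtered: PredictionMatrix | None
    per_site: pd.DataFrame  # site, n, pool_size, effective_pool, singleton, accuracy
    pooled_accuracy: float  # over specimens at non-singleton sites
    unrestricted_accuracy: float


def local_filter(
    preds: PredictionMatrix,
    sites,
    pools: dict[str, list[str]],
    truth,
) -> LocalResult:
    """Rerank each specimen's predictions within its site's species pool.

    Classes outside the pool are removed; the survivors keep their original
    probability ordering (renormalized for reporting).  Sites whose pool
    intersected with the model's classes has exactly one species are
    guaranteed perfect accuracy, so they are excluded from the pooled
    statistic (their per-site accuracy is still reported).
    """
    sites = np.asarray(sites, dtype=object)
    truth = np.asarray(truth, dtype=object)
    if len(sites) != preds.proba.shape[0]:
        raise EvaluateError("site vector does not match prediction rows")
    missing = sorted({s for s in sites if s not in pools})
    if missing:
        raise EvaluateError(f"site(s) absent from pool table: {missing}")
    model_classes = set(preds.classes.astype(str))
    unrestricted = preds.top_labels(1)[:, 0]
    unrestricted_acc = float(np.mean(unrestricted == truth))
    local_top1 = np.empty(len(sites), dtype=object)
    site_rows = []
    eligible = np.zeros(len(sites), dtype=bool)
    for site in pd.unique(sites):
        idx = np.where(sites == site)[0]
        pool = set(pools[site])
        effective = pool & model_classes
        if not effective:
            raise EvaluateError(
                f"site {site!r}: pool shares no species with the model classes"
            )
        sub = PredictionMatrix(
            preds.proba[idx], preds.classes, preds.class_frequency
        ).restrict(effective)
        local_top1[idx] = sub.top_labels(1)[:, 0]
        singleton = len(effective) == 1
        eligible[idx] = not singleton
        site_rows.append(
            {
                "site": site,
                "n": len(idx),
                "pool_size": len(pool),
                "effective_pool": len(effective),
                "singleton": singleton,
                "accuracy": float(np.mean(local_top1[idx] == truth[idx])),
            }
        )
    pooled = (
        float(np.mean(local_top1[eligible] == truth[eligible]))
        if eligible.any()
        else float("nan")
    )
    return LocalResult(
        filtered=None,
        per_site=pd.DataFrame(site_rows),
        pooled_accuracy=pooled,
        unrestricted_accuracy=unrestricted_acc,
    )


# ---------------------------------------------------------------------------
# Novel species


def novel_species_evaluate(
    model, rare: pd.DataFrame, tax: TaxonomyTable, ranks=None
) -> pd.DataFrame:
    """Score forced species-level predictions of never-trained species at the
    ranks where they share a clade with the training set.

    A rank is measurable for a specimen only if its true label at that rank
    is also the lifted label of at least one training species.  Returns one
    row per rank with the measurable count and top-1 accuracy (NaN when no
    specimen is measurable).
    """
    ranks = list(ranks or tax.ranks)
    for sp in pd.unique(rare["species"]):
        if sp not in tax:
            raise EvaluateError(f"rare species {sp!r} missing from taxonomy")
    feats = feature_names()
    pm = model.prediction_matrix(rare[feats].to_numpy(float))
    pred_species = pm.top_labels(1)[:, 0]
    truth_species = rare["species"].to_numpy(dtype=object)
    rows = []
    for rank in ranks:
        training_clades = set(tax.lift([str(c) for c in model.classes_], rank))
        truth_r = np.asarray(tax.lift(list(truth_species), rank), dtype=object)
        pred_r = np.asarray(tax.lift(list(pred_species), rank), dtype=object)
        measurable = np.array([t in training_clades for t in truth_r])
        acc = (
            float(np.mean(pred_r[measurable] == truth_r[measurable]))
            if measurable.any()
            else float("nan")
        )
        rows.append(
            {"rank": rank, "n_measurable": int(measurable.sum()), "accuracy": acc}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Confusion matrices


def confusion_matrix_avg(
    pred_truth_pairs: list[tuple[np.ndarray, np.ndarray]],
    classes=None,
    percent: bool = False,
) -> pd.DataFrame:
    """Cell-wise average confusion matrix over repeats.

    Rows are predicted labels, columns actual labels.  Marginal totals are
    appended as an ``Actual`` row (average test count per class) and a
    ``Predicted`` column (average prediction count per class).  With
    ``percent=True`` cells are expressed as a percentage of their column's
    actual total.
    """
    if classes is None:
        classes = sorted(
            set().union(*(set(p) | set(t) for p, t in pred_truth_pairs))
        )
    classes = list(classes)
    mats = []
    for pred, truth in pred_truth_pairs:
        m = pd.crosstab(
            pd.Series(list(pred), name="predicted"),
            pd.Series(list(truth), name="actual"),
        ).reindex(index=classes, columns=classes, fill_value=0)
        mats.append(m.to_numpy(dtype=float))
    avg = np.mean(mats, axis=0)
    out = pd.DataFrame(avg, index=classes, columns=classes)
    if percent:
        col_tot = out.sum(axis=0)
        out = out.div(col_tot.replace(0, np.nan), axis=1) * 100.0
        return out
    out["Predicted"] = out.sum(axis=1)
    out.loc["Actual"] = out.drop(columns="Predicted").sum(axis=0)
    out.loc["Actual", "Predicted"] = np.nan
    return out


# ---------------------------------------------------------------------------
# Aggregated report


@dataclass
class EvaluationReport:
    """Tidy results of a full experiment.

    ``metrics`` is long-form (algorithm, mode, rank, metric, repeat, value);
    ``local`` per-repeat local accuracy; ``local_sites`` per-site detail;
    ``novel`` per-rank novel-species accuracy per algorithm and repeat;
    ``confusion`` averaged species-level confusion matrices per algorithm.
    """

    metrics: pd.DataFrame
    local: pd.DataFrame
    local_sites: pd.DataFrame
    novel: pd.DataFrame
    confusion: dict[str, pd.DataFrame]
    provenance: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        """Mean of per-repeat values per algorithm x mode x rank x metric."""
        return (
            self.metrics.groupby(["algorithm", "mode", "rank", "metric"], sort=False)[
                "value"
            ]
            .mean()
            .reset_index()
        )

    def to_csv(self, outdir) -> None:
        import json
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.metrics.to_csv(outdir / "metrics.csv", index=False)
        self.summary().to_csv(outdir / "summary.csv", index=False)
        self.local.to_csv(outdir / "local.csv", index=False)
        self.local_sites.to_csv(outdir / "local_sites.csv", index=False)
        self.novel.to_csv(outdir / "novel.csv", index=False)
        for alg, mat in self.confusion.items():
            mat.to_csv(outdir / f"confusion_{alg}.csv")
        (outdir / "run_metadata.json").write_text(
            json.dumps(self.provenance, indent=2, default=str)
        )
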