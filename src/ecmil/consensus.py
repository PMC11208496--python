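"""Patient-grouped 10-fold ensemble and consensus vote refinement.

Patients are partitioned into k (default 10) disjoint groups, stratified by
molecular label; classifier i tests on groups {i, i+1}, validates on
{i+2, i+3} (mod k) and trains on the remaining six — a 60/20/20 split in
which all slides of a patient stay together, so no patient leaks between a
classifier's train and test sets and every group appears in exactly two test
sets.  The ten classifiers then vote on every case; molecularly-NSMP cases
voted p53abn by more than tau (default 7) of the ten are relabeled
"p53abn-like NSMP", and symmetrically p53abn cases voted NSMP by more than
tau classifiers become "NSMP-like p53abn".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import (
    average_precision_score,
    balanced_accuracy_score,
    roc_auc_score,
)

from .varmil import CLASSES, PatchBag, TrainConfig, VarMILModel, train

__all__ = [
    "FoldPlan",
    "EnsembleMetrics",
    "make_group_folds",
    "train_ensemble",
    "vote",
    "prediction_matrix",
    "build_vote_table",
    "aggregate_to_patient",
    "refine_labels",
    "evaluate_ensemble",
    "LABEL_P53ABN_LIKE",
    "LABEL_NSMP_LIKE",
]

LABEL_P53ABN_LIKE = "p53abn-like NSMP"
LABEL_NSMP_LIKE = "NSMP-like p53abn"


@dataclass
class FoldPlan:
    groups: list[list[str]]                 # k disjoint patient groups
    assignments: list[dict[str, list[int]]]  # per classifier: train/val/test group indices
    seed: int

    @property
    def k(self) -> int:
        return len(self.groups)

    def patients_in(self, classifier: int, role: str) -> set[str]:
        return {p for g in self.assignments[classifier][role] for p in self.groups[g]}

    def validate(self) -> None:
        seen: set[str] = set()
        for g in self.groups:
            if seen & set(g):
                raise ValueError("patient assigned to multiple groups")
            seen |= set(g)
        test_counts = np.zeros(self.k, dtype=int)
        for asg in self.assignments:
            roles = asg["train"] + asg["val"] + asg["test"]
            if sorted(roles) != list(range(self.k)):
                raise ValueError("train/val/test must partition the groups")
            test_counts[asg["test"]] += 1
        if not np.all(test_counts == 2):
            raise ValueError("each group must appear in exactly 2 test sets")


def make_group_folds(patients: Sequence[str], labels: Mapping[str, str],
                     k: int = 10, seed: int = 0) -> FoldPlan:
    """Stratified patient-level group folds with the rotation assignment
    test {i, i+1}, val {i+2, i+3}, train the rest (indices mod k)."""
    patients = list(patients)
    if len(patients) < k:
        raise ValueError(f"need at least {k} patients for {k} groups")
    classes = sorted({labels[p] for p in patients})
    if len(classes) < 2:
        raise ValueError("both molecular classes must be present")
    rng = np.random.default_rng(seed)
    groups: list[list[str]] = [[] for _ in range(k)]
    slot = 0
    for cls in classes:
        members = sorted(p for p in patients if labels[p] == cls)
        rng.shuffle(members)
        for p in members:
            groups[slot % k].append(p)
            slot += 1
    assignments = []
    for i in range(k):
        test = [i % k, (i + 1) % k]
        val = [(i + 2) % k, (i + 3) % k]
        trn = [g for g in range(k) if g not in test + val]
        assignments.append({"train": trn, "val": val, "test": test})
    plan = FoldPlan(groups=groups, assignments=assignments, seed=seed)
    plan.validate()
    return plan


def _to_int_label(label: str | int) -> int:
    if isinstance(label, str):
        return CLASSES.index(label)
    return int(label)


def train_ensemble(bags: Sequence[PatchBag], labels: Mapping[str, str | int],
                   plan: FoldPlan, config: TrainConfig) -> list[VarMILModel]:
    """One VarMIL classifier per fold assignment, each trained only on its
    train groups and early-stopped on its validation groups."""
    models = []
    for i, asg in enumerate(plan.assignments):
        train_p = plan.patients_in(i, "train")
        val_p = plan.patients_in(i, "val")
        tr = [(b, _to_int_label(labels[b.patient_id])) for b in bags
              if b.patient_id in train_p]
        va = [(b, _to_int_label(labels[b.patient_id])) for b in bags
              if b.patient_id in val_p]
        cfg = TrainConfig(**{**vars(config), "seed": config.seed + i})
        try:
            models.append(train([b for b, _ in tr], [y for _, y in tr], cfg,
                                [b for b, _ in va], [y for _, y in va]))
        except ValueError as exc:
            raise ValueError(f"classifier {i}: {exc}") from exc
    return models


def vote(models: Sequence[VarMILModel], bag: PatchBag) -> int:
    """Number of models predicting p53abn; ties at probability 0.5 count as
    NSMP (conservative)."""
    if any(m is None for m in models):
        raise ValueError("missing model in ensemble")
    return int(sum(m.predict_proba(bag)[1] > 0.5 for m in models))


def prediction_matrix(models: Sequence[VarMILModel],
                      bags: Sequence[PatchBag]) -> pd.DataFrame:
    """Slide-by-classifier 0/1 p53abn predictions (index slide_id)."""
    rows = {}
    for bag in bags:
        rows[bag.slide_id] = [int(m.predict_proba(bag)[1] > 0.5) for m in models]
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=[f"clf{i}" for i in range(len(models))])
    df.index.name = "slide_id"
    return df


def build_vote_table(models: Sequence[VarMILModel], bags: Sequence[PatchBag],
                     labels: Mapping[str, str], plan: FoldPlan | None = None,
                     test_only: bool = False) -> pd.DataFrame:
    """Per-slide vote counts.

    By default all classifiers vote on every case.  With ``test_only=True``
    (requires a plan) only the classifiers that did not see the case's
    patient during training or validation vote, and ``n_voters`` records how
    many voted.
    """
    if test_only and plan is None:
        raise ValueError("test_only voting requires a fold plan")
    pred = prediction_matrix(models, bags)
    out = []
    for bag in bags:
        row = pred.loc[bag.slide_id]
        if test_only:
            voters = [i for i in range(len(models))
                      if bag.patient_id in plan.patients_in(i, "test")]
        else:
            voters = list(range(len(models)))
        out.append({
            "slide_id": bag.slide_id,
            "patient_id": bag.patient_id,
            "molecular_label": labels[bag.patient_id],
            "votes_p53abn": int(row.iloc[voters].sum()),
            "n_voters": len(voters),
        })
    return pd.DataFrame(out)


def aggregate_to_patient(prediction_df: pd.DataFrame,
                         slide_to_patient: Mapping[str, str],
                         labels: Mapping[str, str]) -> pd.DataFrame:
    """Patient-level vote table: per classifier, a patient's call is the
    majority over their slides (ties count as NSMP), then calls are summed."""
    missing = [s for s in prediction_df.index if s not in slide_to_patient]
    if missing:
        raise ValueError(f"unmapped slide(s): {missing[:3]}")
    df = prediction_df.copy()
    df["patient_id"] = [slide_to_patient[s] for s in df.index]
    clf_cols = [c for c in prediction_df.columns]
    rows = []
    for pid, grp in df.groupby("patient_id", sort=True):
        calls = (grp[clf_cols].mean(axis=0) > 0.5).astype(int)  # tie -> NSMP
        rows.append({
            "patient_id": pid,
            "molecular_label": labels[pid],
            "votes_p53abn": int(calls.sum()),
            "n_voters": len(clf_cols),
        })
    return pd.DataFrame(rows)


def refine_labels(vote_table: pd.DataFrame, tau: int = 7) -> pd.DataFrame:
    """Assign refined labels from vote counts.

    Molecularly NSMP with votes_p53abn > tau (strict) -> "p53abn-like NSMP";
    molecularly p53abn with NSMP votes > tau -> "NSMP-like p53abn".  When
    fewer than the full ensemble voted (test-only mode) the threshold is the
    same fraction of the actual voters.
    """
    if not 0 <= tau <= 10:
        raise ValueError(f"tau={tau} outside [0, 10]")
    df = vote_table.copy()
    refined = []
    for _, row in df.iterrows():
        n = int(row["n_voters"])
        if n == 0:
            raise ValueError("case with no voters")
        cut = tau * n / 10.0 if n != 10 else float(tau)
        v = int(row["votes_p53abn"])
        if row["molecular_label"] == "NSMP":
            refined.append(LABEL_P53ABN_LIKE if v > cut else "NSMP")
        else:
            refined.append(LABEL_NSMP_LIKE if (n - v) > cut else "p53abn")
    df["refined_label"] = refined
    return df


@dataclass
class EnsembleMetrics:
    per_classifier: pd.DataFrame  # balanced_accuracy, auroc, auprc per classifier
    mean_balanced_accuracy: float
    mean_auroc: float
    mean_auprc: float


def evaluate_ensemble(models: Sequence[VarMILModel], plan: FoldPlan,
                      bags: Sequence[PatchBag],
                      labels: Mapping[str, str | int]) -> EnsembleMetrics:
    """Each classifier evaluated on its own test groups, then averaged."""
    rows = []
    for i, model in enumerate(models):
        test_p = plan.patients_in(i, "test")
        test_bags = [b for b in bags if b.patient_id in test_p]
        y = np.array([_to_int_label(labels[b.patient_id]) for b in test_bags])
        if len(np.unique(y)) < 2:
            warnings.warn(f"classifier {i}: single-class test set, metrics undefined")
            rows.append({"classifier": i, "balanced_accuracy": np.nan,
                         "auroc": np.nan, "auprc": np.nan})
            continue
        p = np.array([model.predict_proba(b)[1] for b in test_bags])
        yhat = (p > 0.5).astype(int)
        rows.append({
            "classifier": i,
            "balanced_accuracy": balanced_accuracy_score(y, yhat),
            "auroc": roc_auc_score(y, p),
            "auprc": average_precision_score(y, p),
        })
    df = pd.DataFrame(rows)
    return EnsembleMetrics(
        per_classifier=df,
        mean_balanced_accuracy=float(np.nanmean(df["balanced_accuracy"])),
        mean_auroc=float(np.nanmean(df["auroc"])),
        mean_auprc=float(np.nanmean(df["auprc"])),
    )
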