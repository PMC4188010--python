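"""Posterior scoring and ranking of droplets, wells and plates.

A two-class random forest is trained on texton histograms labelled
interesting (crystals or crystalline behaviour; human scores of 3 and
above) versus uninteresting (scores below 3 or unscored).  No
classification threshold is applied: the posterior probability of the
interesting class is the droplet's score and droplets are viewed in
descending score order.  The sorted scores of one plate form its profile.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "INTERESTING_SCORE_CUTOFF",
    "DEFAULT_CUTOFFS",
    "labels_from_human_scores",
    "train_ranker",
    "cross_validate_ranker",
    "score_droplets",
    "rank_plate",
    "profile_summary",
    "rank_enrichment",
]

#: human score at/above which a droplet counts as interesting
INTERESTING_SCORE_CUTOFF = 3
#: default score cutoffs of the profile trade-off table
DEFAULT_CUTOFFS = (0.8, 0.5, 0.2, 0.1, 0.05, 0.01)
DEFAULT_N_TREES = 500


def labels_from_human_scores(scores) -> np.ndarray:
    """Map optional 1-10 human scores to interesting/uninteresting labels.

    Scores >= 3 (microcrystals and better) are interesting; lower or missing
    scores are uninteresting.
    """
    s = pd.Series(scores)
    interesting = s.notna() & (s >= INTERESTING_SCORE_CUTOFF)
    return np.where(interesting, "interesting", "uninteresting")


def _hist_matrix(histograms) -> np.ndarray:
    rows = [
        h.counts if hasattr(h, "counts") else np.asarray(h, float)
        for h in histograms
    ]
    return np.vstack(rows).astype(float)


def train_ranker(
    histograms, labels, n_trees: int = DEFAULT_N_TREES, seed: int = 0
) -> RandomForestClassifier:
    """Seeded two-class random forest on raw texton histogram counts."""
    X = _hist_matrix(histograms)
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError("training data must contain both classes")
    clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    clf.fit(X, y)
    return clf


def cross_validate_ranker(
    histograms,
    labels,
    n_folds: int = 10,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
) -> pd.Series:
    """Stratified k-fold ROC AUC and accuracy of the ranker."""
    X = _hist_matrix(histograms)
    y = np.asarray(labels)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    aucs, accs = [], []
    for tr, te in skf.split(X, y):
        clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
        clf.fit(X[tr], y[tr])
        pos = list(clf.classes_).index("interesting")
        p = clf.predict_proba(X[te])[:, pos]
        aucs.append(roc_auc_score(y[te] == "interesting", p))
        accs.append((clf.predict(X[te]) == y[te]).mean())
    return pd.Series(
        {
            "auc_mean": float(np.mean(aucs)),
            "auc_std": float(np.std(aucs)),
            "accuracy_mean": float(np.mean(accs)),
            "accuracy_std": float(np.std(accs)),
        }
    )


def score_droplets(
    model: RandomForestClassifier, histograms, manifest: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Posterior probability of the interesting class per droplet.

    With a manifest (columns image_id, plate, well, subwell) the identity
    columns are carried through.  Scores are used directly as ranking keys;
    no threshold is applied.
    """
    X = _hist_matrix(histograms)
    pos = list(model.classes_).index("interesting")
    scores = model.predict_proba(X)[:, pos]
    if manifest is not None:
        out = manifest.reset_index(drop=True).copy()
    else:
        out = pd.DataFrame({"image_id": [f"img{i:05d}" for i in range(len(scores))]})
    out["score"] = scores
    return out


def rank_plate(scores: pd.DataFrame, mode: str = "by_subwell") -> pd.DataFrame:
    """Viewing order within each plate.

    ``by_subwell`` ranks individual droplets; ``by_well`` aggregates the
    subwells of a well by their maximum score.  Ranks are 1-based in
    descending score, ties broken by image id (or well id) for a
    reproducible order.
    """
    if mode not in ("by_subwell", "by_well"):
        raise ValueError("mode must be 'by_subwell' or 'by_well'")
    df = scores.copy()
    if mode == "by_well":
        keep = {"plate", "well", "score"}
        agg = {"score": "max"}
        if "true_class" in df.columns:
            agg["true_class"] = lambda s: (
                "crystal_bearing" if s.isin(_CRYSTAL_CLASSES).any() else "other"
            )
        if "interesting" in df.columns:
            agg["interesting"] = "max"
        df = df.groupby(["plate", "well"], as_index=False).agg(agg)
        sort_id = "well"
    else:
        sort_id = "image_id"
    df = df.sort_values(
        ["plate", "score", sort_id], ascending=[True, False, True]
    ).reset_index(drop=True)
    df["rank"] = df.groupby("plate").cumcount() + 1
    return df


_CRYSTAL_CLASSES = ("crystal", "microcrystal_shower")


def rank_enrichment(ranked: pd.DataFrame, is_crystal) -> pd.Series:
    """One-sided Wilcoxon rank-sum test that crystal-bearing droplets sit
    earlier in the viewing order than the rest."""
    is_crystal = np.asarray(is_crystal, dtype=bool)
    r = ranked["rank"].to_numpy()
    stat = stats.mannwhitneyu(
        r[is_crystal], r[~is_crystal], alternative="less"
    )
    return pd.Series(
        {
            "mean_rank_crystal": float(r[is_crystal].mean()),
            "mean_rank_other": float(r[~is_crystal].mean()),
            "p_value": float(stat.pvalue),
        }
    )


def profile_summary(
    ranked: pd.DataFrame,
    cutoffs=DEFAULT_CUTOFFS,
    crystal_col: str = "interesting",
) -> pd.DataFrame:
    """Cutoff trade-off over a batch of plates.

    For each score cutoff: the fraction of plates where at least one truly
    crystal-bearing droplet scores above the cutoff (those crystals would be
    found by viewing only images above the cutoff), and the mean fraction of
    uninteresting droplets per plate at or below it (droplets one is spared
    from viewing).  ``crystal_col`` is a boolean column of ``ranked``.
    Also reports the rank of the first crystal per plate.
    """
    df = ranked.copy()
    df["_crystal"] = df[crystal_col].astype(bool)
    plates = df.groupby("plate")
    rows = []
    for cutoff in cutoffs:
        found = plates.apply(
            lambda g: bool((g["_crystal"] & (g["score"] > cutoff)).any()),
            include_groups=False,
        )
        unseen = plates.apply(
            lambda g: (
                (~g["_crystal"] & (g["score"] <= cutoff)).sum()
                / max((~g["_crystal"]).sum(), 1)
            ),
            include_groups=False,
        )
        rows.append(
            {
                "cutoff": cutoff,
                "plates_found_frac": float(found.mean()),
                "mean_unseen_frac": float(unseen.mean()),
            }
        )
    summary = pd.DataFrame(rows)
    first = plates.apply(
        lambda g: (
            int(g.loc[g["_crystal"], "rank"].min()) if g["_crystal"].any() else -1
        ),
        include_groups=False,
    )
    summary.attrs["first_crystal_rank"] = first.to_dict()
    return summary
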