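"""Comparative genomics of auxotrophy: COG association, classification, usage.

Given a strains x COG presence/absence matrix with per-vitamin
auxotroph/prototroph labels and a COG -> pathway map, this module

* tests each pathway-mapped COG for differential presence between
  auxotrophs and prototrophs (2x2 chi-squared, Benjamini-Hochberg FDR),
* summarises pathway completeness (fraction of a pathway's COGs present per
  strain) and pathway-level differential presence (pathways where more than
  a fraction of genes are significant),
* trains and applies small decision-tree classifiers (depth <= 3) on binary
  COG features, with a random-feature baseline over many draws,
* counts coenzyme-dependent reactions from an exported reaction -> cofactor
  table and compares usage between the two groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import accuracy_score, precision_score, recall_score
from sklearn.model_selection import train_test_split
from sklearn.tree import DecisionTreeClassifier
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CogPresenceMatrix",
    "AssociationRecord",
    "PathwayDiff",
    "TreeClassifier",
    "cog_association",
    "association_frame",
    "benjamini_hochberg",
    "pathway_completeness",
    "pathway_differential",
    "train_auxotrophy_classifier",
    "random_feature_baseline",
    "predict_auxotrophy",
    "count_coenzyme_reactions",
    "compare_usage",
]

COENZYME_VOCABULARY = ("NAD(H)", "NADP(H)", "FAD(H)", "FMN", "biotin", "TPP", "CoA")


@dataclass
class CogPresenceMatrix:
    """Strains x COG booleans with a pathway map and per-vitamin labels.

    ``presence``: boolean DataFrame, index = strain IDs, columns = COG IDs.
    ``pathway_map``: COG ID -> pathway name; analyses are restricted to
    mapped COGs. ``labels``: DataFrame indexed by strain with one column per
    vitamin, values in {"auxotroph", "prototroph", "unknown"}.
    """

    presence: pd.DataFrame
    pathway_map: dict[str, str]
    labels: pd.DataFrame

    def __post_init__(self) -> None:
        if self.presence.index.duplicated().any():
            raise ValueError("duplicate strain IDs")
        if self.presence.columns.duplicated().any():
            raise ValueError("duplicate COG IDs")
        self.presence = self.presence.astype(bool)

    @property
    def mapped_cogs(self) -> list[str]:
        return [c for c in self.presence.columns if c in self.pathway_map]

    def classes(self, vitamin: str) -> tuple[pd.Index, pd.Index]:
        """Strain IDs of the auxotroph and prototroph class for a vitamin."""
        if vitamin not in self.labels.columns:
            raise KeyError(f"no labels for vitamin {vitamin!r}")
        lab = self.labels[vitamin].reindex(self.presence.index)
        return (
            self.presence.index[(lab == "auxotroph").to_numpy()],
            self.presence.index[(lab == "prototroph").to_numpy()],
        )


@dataclass(frozen=True)
class AssociationRecord:
    """One COG's 2x2 differential-presence test result."""

    cog: str
    counts: tuple[int, int, int, int]  # aux_present, aux_absent, proto_present, proto_absent
    chi2_stat: float
    p_value: float
    q_value: float
    direction: str  # more_in_auxotrophs / more_in_prototrophs / none
    pct_present_aux: float
    pct_present_proto: float
    flagged: bool = False  # constant column or an expected cell count < 1


@dataclass(frozen=True)
class PathwayDiff:
    pathway: str
    n_genes: int
    n_differential: int
    fraction: float
    enriched_group: str


@dataclass
class TreeClassifier:
    """A fitted depth-limited decision tree over binary COG features."""

    model: DecisionTreeClassifier
    features: tuple[str, ...]
    vitamin: str
    metrics: dict[str, float] = field(default_factory=dict)
    feature_set: str = "selected"
    seed: int = 0


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, order preserving."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _chi2_2x2(table: np.ndarray, correction: bool) -> tuple[float, float, bool]:
    """chi2 statistic, p-value and a small-expected-count flag."""
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        # degenerate margin (constant COG): independence holds by convention
        return 0.0, 1.0, True
    chi2, p, _, expected = stats.chi2_contingency(table, correction=correction)
    return float(chi2), float(p), bool(expected.min() < 1.0)


def cog_association(
    matrix: CogPresenceMatrix,
    vitamin: str,
    correction: bool = False,
    cogs: Sequence[str] | None = None,
) -> list[AssociationRecord]:
    """Per-COG differential presence between auxotrophs and prototrophs.

    A 2x2 chi-squared test (Yates continuity correction off by default) is
    run for every pathway-mapped COG; p-values are BH-adjusted over the
    tested set. COGs constant across all strains are emitted with p = 1 and
    flagged rather than dropped; records with an expected cell count < 1 are
    flagged but tested.
    """
    aux_idx, proto_idx = matrix.classes(vitamin)
    if len(aux_idx) == 0 or len(proto_idx) == 0:
        raise ValueError(f"both classes must be non-empty for vitamin {vitamin!r}")
    universe = list(cogs) if cogs is not None else matrix.mapped_cogs
    missing = [c for c in universe if c not in matrix.presence.columns]
    if missing:
        raise KeyError(f"COGs not in matrix: {missing[:5]}")

    aux = matrix.presence.loc[aux_idx, universe].to_numpy()
    proto = matrix.presence.loc[proto_idx, universe].to_numpy()
    n_aux, n_proto = aux.shape[0], proto.shape[0]

    raw: list[tuple[str, tuple[int, int, int, int], float, float, bool]] = []
    for j, cog in enumerate(universe):
        ap = int(aux[:, j].sum())
        pp = int(proto[:, j].sum())
        table = np.array([[ap, n_aux - ap], [pp, n_proto - pp]])
        chi2, p, flagged = _chi2_2x2(table, correction)
        raw.append((cog, (ap, n_aux - ap, pp, n_proto - pp), chi2, p, flagged))

    q = benjamini_hochberg([r[3] for r in raw])
    records = []
    for (cog, counts, chi2, p, flagged), qv in zip(raw, q):
        pct_aux = 100.0 * counts[0] / n_aux
        pct_proto = 100.0 * counts[2] / n_proto
        if pct_aux > pct_proto:
            direction = "more_in_auxotrophs"
        elif pct_proto > pct_aux:
            direction = "more_in_prototrophs"
        else:
            direction = "none"
        records.append(
            AssociationRecord(
                cog=cog,
                counts=counts,
                chi2_stat=chi2,
                p_value=p,
                q_value=float(qv),
                direction=direction,
                pct_present_aux=pct_aux,
                pct_present_proto=pct_proto,
                flagged=flagged,
            )
        )
    return records


def association_frame(records: Sequence[AssociationRecord]) -> pd.DataFrame:
    """Tabular view of association records (one row per COG)."""
    return pd.DataFrame(
        {
            "cog": [r.cog for r in records],
            "aux_present": [r.counts[0] for r in records],
            "aux_absent": [r.counts[1] for r in records],
            "proto_present": [r.counts[2] for r in records],
            "proto_absent": [r.counts[3] for r in records],
            "chi2": [r.chi2_stat for r in records],
            "p": [r.p_value for r in records],
            "q": [r.q_value for r in records],
            "direction": [r.direction for r in records],
            "pct_aux": [r.pct_present_aux for r in records],
            "pct_proto": [r.pct_present_proto for r in records],
            "flagged": [r.flagged for r in records],
        }
    )


def pathway_completeness(matrix: CogPresenceMatrix) -> pd.DataFrame:
    """Fraction of each pathway's mapped COGs present in each strain."""
    groups: dict[str, list[str]] = {}
    for cog in matrix.mapped_cogs:
        groups.setdefault(matrix.pathway_map[cog], []).append(cog)
    if not groups:
        raise ValueError("no pathway-mapped COGs in the matrix")
    out = {pw: matrix.presence[cogs].mean(axis=1) for pw, cogs in groups.items()}
    return pd.DataFrame(out)


def pathway_differential(
    records: Sequence[AssociationRecord],
    matrix: CogPresenceMatrix,
    cutoff: float = 0.20,
    alpha: float = 0.05,
) -> list[PathwayDiff]:
    """Pathways where strictly more than ``cutoff`` of genes are significant.

    ``n_genes`` counts the tested (record-bearing) COGs mapped to the
    pathway; the enriched group is the majority direction among the
    pathway's significant COGs.
    """
    if not (0 < cutoff < 1):
        raise ValueError("cutoff must lie in (0, 1)")
    by_pathway: dict[str, list[AssociationRecord]] = {}
    for r in records:
        pw = matrix.pathway_map.get(r.cog)
        if pw is not None:
            by_pathway.setdefault(pw, []).append(r)
    out = []
    for pw, recs in sorted(by_pathway.items()):
        sig = [r for r in recs if r.q_value < alpha]
        frac = len(sig) / len(recs)
        if frac > cutoff:
            n_proto_dir = sum(r.direction == "more_in_prototrophs" for r in sig)
            n_aux_dir = sum(r.direction == "more_in_auxotrophs" for r in sig)
            enriched = (
                "more_in_prototrophs" if n_proto_dir >= n_aux_dir else "more_in_auxotrophs"
            )
            out.append(PathwayDiff(pw, len(recs), len(sig), frac, enriched))
    return out


def _split_xy(
    matrix: CogPresenceMatrix,
    vitamin: str,
    features: Sequence[str],
) -> tuple[np.ndarray, np.ndarray, pd.Index]:
    aux_idx, proto_idx = matrix.classes(vitamin)
    strains = aux_idx.append(proto_idx)
    for c in (aux_idx, proto_idx):
        if len(c) < 2:
            raise ValueError("need >= 2 strains per class")
    missing = [f for f in features if f not in matrix.presence.columns]
    if missing:
        raise KeyError(f"features not in matrix: {missing}")
    X = matrix.presence.loc[strains, list(features)].to_numpy(dtype=int)
    y = np.array(["auxotroph"] * len(aux_idx) + ["prototroph"] * len(proto_idx))
    return X, y, strains


def train_auxotrophy_classifier(
    matrix: CogPresenceMatrix,
    vitamin: str,
    features: Sequence[str],
    test_fraction: float = 0.4,
    max_depth: int = 3,
    seed: int = 0,
) -> TreeClassifier:
    """Train a depth-limited decision tree on binary COG presence features.

    The strains are split into stratified (class-balanced) train/test sets
    with ``test_fraction`` held out; accuracy, precision and recall on the
    held-out set (auxotroph = positive class) are stored in ``metrics``
    alongside the training accuracy.
    """
    X, y, _ = _split_xy(matrix, vitamin, features)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=test_fraction, stratify=y, random_state=seed
    )
    for part in (y_tr, y_te):
        if len(np.unique(part)) < 2:
            raise ValueError("a class is absent from the train or test split")
    model = DecisionTreeClassifier(max_depth=max_depth, random_state=seed)
    model.fit(X_tr, y_tr)
    pred = model.predict(X_te)
    metrics = {
        "accuracy": float(accuracy_score(y_te, pred)),
        "precision": float(
            precision_score(y_te, pred, pos_label="auxotroph", zero_division=0)
        ),
        "recall": float(recall_score(y_te, pred, pos_label="auxotroph", zero_division=0)),
        "train_accuracy": float(accuracy_score(y_tr, model.predict(X_tr))),
    }
    return TreeClassifier(
        model=model,
        features=tuple(features),
        vitamin=vitamin,
        metrics=metrics,
        feature_set="selected",
        seed=seed,
    )


def random_feature_baseline(
    matrix: CogPresenceMatrix,
    vitamin: str,
    n_features: int,
    n_randomizations: int = 500,
    test_fraction: float = 0.4,
    max_depth: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Null classifier performance over random COG feature draws.

    Repeats the train/test procedure ``n_randomizations`` times, each with
    ``n_features`` COGs sampled without replacement from the pathway-mapped
    universe and a fresh stratified split; returns one metrics row per draw.
    """
    rng = np.random.default_rng(seed)
    universe = matrix.mapped_cogs
    if n_features > len(universe):
        raise ValueError("more features requested than mapped COGs available")
    rows = []
    for i in range(n_randomizations):
        feats = list(rng.choice(universe, size=n_features, replace=False))
        clf = train_auxotrophy_classifier(
            matrix,
            vitamin,
            feats,
            test_fraction=test_fraction,
            max_depth=max_depth,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        rows.append({"draw": i, **clf.metrics})
    return pd.DataFrame(rows)


def predict_auxotrophy(classifier: TreeClassifier, matrix: CogPresenceMatrix) -> pd.Series:
    """Deterministic tree traversal for every strain in the matrix."""
    missing = [f for f in classifier.features if f not in matrix.presence.columns]
    if missing:
        raise KeyError(f"matrix lacks classifier features: {missing}")
    X = matrix.presence[list(classifier.features)].to_numpy(dtype=int)
    return pd.Series(classifier.model.predict(X), index=matrix.presence.index, name="predicted")


def count_coenzyme_reactions(
    reaction_table: pd.DataFrame,
    vocabulary: Sequence[str] = COENZYME_VOCABULARY,
    strains: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Count, per strain, the reactions whose cofactor set includes each coenzyme.

    ``reaction_table`` has columns ``strain``, ``reaction_id`` and
    ``cofactors`` (semicolon-separated names; a reaction may count toward
    several coenzymes). Unknown cofactor names raise. An empty table yields
    all-zero counts (over ``strains`` if given).
    """
    vocab = list(vocabulary)
    index = pd.Index(strains if strains is not None else [], name="strain")
    if not reaction_table.empty:
        required = {"strain", "reaction_id", "cofactors"}
        missing = required - set(reaction_table.columns)
        if missing:
            raise ValueError(f"reaction_table missing columns: {sorted(missing)}")
        index = index.union(pd.Index(reaction_table["strain"].unique()), sort=True)
    counts = pd.DataFrame(0, index=index, columns=vocab, dtype=int)
    for _, row in reaction_table.iterrows():
        names = [c.strip() for c in str(row["cofactors"]).split(";") if c.strip()]
        unknown = [c for c in names if c not in vocab]
        if unknown:
            raise ValueError(f"cofactors not in vocabulary: {unknown}")
        for c in set(names):
            counts.loc[row["strain"], c] += 1
    return counts


def compare_usage(
    usage: pd.DataFrame,
    labels: Mapping[str, str] | pd.Series,
) -> pd.DataFrame:
    """Per-coenzyme group difference in reaction counts, with chi2 p-values.

    For each coenzyme, reports the auxotroph and prototroph mean counts, the
    percent difference of group means (relative to prototrophs), the
    direction, and a chi-squared p-value on the 2x2 table of summed counts
    (this coenzyme vs all other coenzymes, by group).
    """
    lab = pd.Series(labels).reindex(usage.index)
    aux = usage[(lab == "auxotroph").to_numpy()]
    proto = usage[(lab == "prototroph").to_numpy()]
    if aux.empty or proto.empty:
        raise ValueError("both groups must be non-empty")
    rows = []
    aux_tot, proto_tot = aux.to_numpy().sum(), proto.to_numpy().sum()
    for c in usage.columns:
        ma, mp = float(aux[c].mean()), float(proto[c].mean())
        sa, sp = int(aux[c].sum()), int(proto[c].sum())
        table = np.array([[sa, aux_tot - sa], [sp, proto_tot - sp]])
        _, p, _ = _chi2_2x2(table, correction=False)
        rows.append(
            {
                "coenzyme": c,
                "mean_aux": ma,
                "mean_proto": mp,
                "pct_difference": 100.0 * (ma - mp) / mp if mp > 0 else np.nan,
                "direction": (
                    "more_in_auxotrophs"
                    if ma > mp
                    else "more_in_prototrophs" if mp > ma else "none"
                ),
                "p_value": p,
            }
        )
    return pd.DataFrame(rows).set_index("coenzyme")
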