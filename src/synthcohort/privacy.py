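"""Confidentiality and plausibility audits.

Confidentiality asks two questions of an artificial cohort:

* filter similarity — what share of artificial records are NOT exact
  duplicates of any real record (on all decoded fields)?  100% means no
  real patient reappears verbatim.
* degree of anonymization — in the min-max-scaled encoded space, are
  artificial records farther (Euclidean) from their nearest real record
  than real records are from each other (leave-one-out)?  A median ratio
  >= 1 flags the cohort anonymized.

Plausibility is judged by blinded experts labelling a balanced sample of
real and artificial patients; their chance-corrected agreement with the
truth is Cohen's kappa with an asymptotic (Fleiss-Cohen-Everitt) 95% CI.
kappa below 0.2 is read as the expert being unable to tell the cohorts
apart ("indistinguishable").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .encoding import TabularProcessor
from .schema import CohortTable, SchemaError

KAPPA_INDISTINGUISHABLE = 0.2
KAPPA_DISTINGUISHABLE = 0.6


@dataclass
class PrivacyReport:
    filter_similarity_score: float
    n_exact_matches: int
    match_rows: list[int] = field(default_factory=list)
    nn_distances_art_to_real: np.ndarray | None = None
    nn_distances_real_loo: np.ndarray | None = None
    median_art_to_real: float | None = None
    median_real_loo: float | None = None
    anonymization_ratio: float | None = None
    anonymized: bool | None = None

    def to_dict(self) -> dict:
        return {
            "filter_similarity_score": self.filter_similarity_score,
            "n_exact_matches": self.n_exact_matches,
            "median_art_to_real_nn_distance": self.median_art_to_real,
            "median_real_loo_nn_distance": self.median_real_loo,
            "anonymization_ratio": self.anonymization_ratio,
            "anonymized": self.anonymized,
        }


@dataclass
class AgreementResult:
    kappa: float
    ci_low: float
    ci_high: float
    n_items: int
    interpretation: str

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def _row_keys(table: CohortTable) -> pd.Series:
    return pd.Series(
        list(map(tuple, table.data.astype(str).itertuples(index=False, name=None)))
    )


def filter_similarity_score(
    real: CohortTable,
    artificial: CohortTable,
    distance_threshold: float | None = None,
    processor: TabularProcessor | None = None,
) -> tuple[float, list[int]]:
    """Percentage of artificial records not matching any real record.

    A match is exact equality on every decoded field.  Optionally a
    distance-threshold mode treats an artificial record as matching when
    its Euclidean distance to the nearest real record in the encoded space
    is below ``distance_threshold`` (requires a fitted ``processor``).
    """
    if real.schema.names != artificial.schema.names:
        raise SchemaError("cohorts must share a schema")
    if len(artificial) == 0:
        raise ValueError("artificial cohort is empty")
    if distance_threshold is not None:
        if processor is None:
            raise ValueError("distance-threshold mode needs a fitted processor")
        Xr = processor.transform(real).values
        Xa = processor.transform(artificial).values
        d, _ = cKDTree(Xr).query(Xa, k=1)
        matched = d < distance_threshold
    else:
        real_keys = set(_row_keys(real))
        matched = _row_keys(artificial).isin(real_keys).to_numpy()
    rows = [int(i) for i in np.flatnonzero(matched)]
    score = 100.0 * (1.0 - len(rows) / len(artificial))
    return score, rows


def anonymization_degree(
    real: CohortTable,
    artificial: CohortTable,
    processor: TabularProcessor,
) -> PrivacyReport:
    """Nearest-neighbour distance audit in the scaled encoded space.

    Distances use the real cohort's scaler state so both cohorts live in
    the same [0,1]-per-column geometry and no single wide-range numeric
    dominates the Euclidean norm.
    """
    if real.schema.names != artificial.schema.names:
        raise SchemaError("cohorts must share a schema")
    if len(real) < 2:
        raise ValueError("need >= 2 real records for leave-one-out distances")
    if len(artificial) == 0:
        raise ValueError("artificial cohort is empty")
    Xr = processor.transform(real).values
    Xa = processor.transform(artificial).values
    tree = cKDTree(Xr)
    d_art, _ = tree.query(Xa, k=1)
    d_loo_pair, _ = tree.query(Xr, k=2)
    d_loo = d_loo_pair[:, 1]  # nearest OTHER real record
    med_a, med_r = float(np.median(d_art)), float(np.median(d_loo))
    ratio = float(med_a / med_r) if med_r > 0 else float("inf")
    score, rows = filter_similarity_score(real, artificial)
    return PrivacyReport(
        filter_similarity_score=score,
        n_exact_matches=len(rows),
        match_rows=rows,
        nn_distances_art_to_real=d_art,
        nn_distances_real_loo=d_loo,
        median_art_to_real=med_a,
        median_real_loo=med_r,
        anonymization_ratio=ratio,
        anonymized=bool(ratio >= 1.0),
    )


# --- Cohen's kappa --------------------------------------------------------

def cohen_kappa(rater_labels, truth) -> AgreementResult:
    """Cohen's kappa of one rater against ground truth, with 95% CI.

    Both inputs are equal-length sequences of binary labels (any two
    values).  kappa = (p_o - p_e) / (1 - p_e) with p_e from the marginal
    products; the CI uses the Fleiss-Cohen-Everitt large-sample standard
    error.  Interpretation follows the kappa < 0.2 convention for raters
    unable to distinguish the two classes.
    """
    r = np.asarray(rater_labels)
    t = np.asarray(truth)
    if r.shape != t.shape or r.ndim != 1:
        raise ValueError("rater and truth must be equal-length 1-d sequences")
    n = len(r)
    if n < 10:
        raise ValueError("need at least 10 items")
    cats = sorted(set(r.tolist()) | set(t.tolist()))
    if len(cats) > 2:
        raise ValueError("labels must be binary")
    k = len(cats)
    idx = {c: i for i, c in enumerate(cats)}
    P = np.zeros((k, k))
    for ri, ti in zip(r, t):
        P[idx[ri], idx[ti]] += 1
    P /= n
    row, col = P.sum(axis=1), P.sum(axis=0)
    p_o = float(np.trace(P))
    p_e = float(row @ col)
    if p_e >= 1.0:
        raise ValueError("degenerate marginals: p_e = 1, kappa undefined")
    kappa = (p_o - p_e) / (1.0 - p_e)

    # Fleiss, Cohen & Everitt large-sample variance
    A = sum(
        P[i, i] * ((1 - p_e) - (row[i] + col[i]) * (1 - p_o)) ** 2
        for i in range(k)
    )
    B = (1 - p_o) ** 2 * sum(
        P[i, j] * (col[i] + row[j]) ** 2
        for i in range(k)
        for j in range(k)
        if i != j
    )
    C = (p_o * p_e - 2 * p_e + p_o) ** 2
    var = max((A + B - C) / (n * (1 - p_e) ** 4), 0.0)
    se = float(np.sqrt(var))
    ci_low, ci_high = kappa - 1.96 * se, kappa + 1.96 * se

    if kappa < KAPPA_INDISTINGUISHABLE:
        interp = "indistinguishable"
    elif kappa < KAPPA_DISTINGUISHABLE:
        interp = "partial"
    else:
        interp = "distinguishable"
    return AgreementResult(
        kappa=float(kappa),
        ci_low=float(min(ci_low, kappa)),
        ci_high=float(max(ci_high, kappa)),
        n_items=n,
        interpretation=interp,
    )


def categorization_sheet(
    real: CohortTable,
    artificial: CohortTable,
    n_items: int = 100,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Blinded expert-categorization materials.

    Samples ``n_items/2`` patients from each cohort, shuffles them
    (seeded) and returns (sheet, key): the sheet carries item IDs plus all
    clinical fields and no provenance; the key maps item IDs to
    {real, artificial}.  Completed sheets feed :func:`cohen_kappa`.
    """
    if n_items % 2 != 0:
        raise ValueError("n_items must be even (balanced sample required)")
    half = n_items // 2
    if len(real) < half or len(artificial) < half:
        raise ValueError("cohorts too small for the requested sheet")
    rng = np.random.default_rng(seed)
    ri = rng.choice(len(real), size=half, replace=False)
    ai = rng.choice(len(artificial), size=half, replace=False)
    rows = pd.concat(
        [real.data.iloc[ri], artificial.data.iloc[ai]], ignore_index=True
    )
    truth = np.array(["real"] * half + ["artificial"] * half, dtype=object)
    order = rng.permutation(n_items)
    rows = rows.iloc[order].reset_index(drop=True)
    truth = truth[order]
    ids = [f"item_{i + 1:04d}" for i in range(n_items)]
    sheet = rows.copy()
    sheet.insert(0, "item_id", ids)
    key = pd.DataFrame({"item_id": ids, "truth": truth})
    return sheet, key
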