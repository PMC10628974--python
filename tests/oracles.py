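"""Independent reference implementations used only to cross-check the package.

Everything here deliberately avoids the package's own code paths: the score
oracle re-reads the registry YAML and evaluates it with its own dict logic,
the AUC oracle counts concordant pairs exhaustively, and the curve-comparison
oracle is a permutation test. Slow and simple on purpose.
"""

from __future__ import annotations

import itertools

import numpy as np
import yaml


# ---------------------------------------------------------------------------
# config-driven brute-force scale evaluator

def load_registry_yaml(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def brute_force_total(raw_registry: dict, scale: str, values: dict) -> float:
    """Total score for a dict of field values (None = missing, omitted).

    Implements the registry semantics from scratch: banded lookups, simple
    comparisons, any_of, count_ge; factors with missing inputs contribute
    nothing (omit-factor policy).
    """
    total = 0.0
    for factor in raw_registry[scale]["factors"]:
        op = factor["op"]
        if op == "age_sex_band":
            age = values.get(factor["field"])
            sex = values.get(factor.get("sex_field", "sex"))
            if age is None or sex is None:
                continue
            for band in factor["bands"]:
                if band["min"] <= age < band["max"]:
                    total += band[sex]
                    break
        elif op == "band":
            v = values.get(factor["field"])
            if v is None:
                continue
            for band in factor["bands"]:
                if band["min"] <= v < band["max"]:
                    total += band["points"]
                    break
        elif op == "any_of":
            terms = factor["terms"]
            present = [t for t in terms if values.get(t["field"]) is not None]
            if not present:
                continue
            if any(_cmp(values[t["field"]], t["op"], t.get("cutoff")) for t in present):
                total += factor["points"]
        elif op == "count_ge":
            vals = [values.get(f) for f in factor["fields"]]
            if any(v is None for v in vals):
                continue
            if sum(bool(v) for v in vals) >= factor["cutoff"]:
                total += factor["points"]
        else:
            v = values.get(factor["field"])
            if v is None:
                continue
            if _cmp(v, op, factor.get("cutoff")):
                total += factor["points"]
    return total


def _cmp(value, op, cutoff):
    if op == "ge":
        return value >= cutoff
    if op == "gt":
        return value > cutoff
    if op == "le":
        return value <= cutoff
    if op == "lt":
        return value < cutoff
    if op == "eq":
        return value == cutoff
    if op == "flag":
        return bool(value)
    raise ValueError(op)


# ---------------------------------------------------------------------------
# exhaustive pair-count AUC

def pair_count_auc(scores, labels) -> float:
    """AUC as the concordant-pair fraction over all pos x neg pairs,
    counting ties as 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    mask = labels.astype(bool) if labels.dtype.kind in "bifu" else labels == "decline"
    pos, neg = scores[mask], scores[~mask]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("need both classes")
    wins = 0.0
    for x, y in itertools.product(pos, neg):
        if x > y:
            wins += 1.0
        elif x == y:
            wins += 0.5
    return wins / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# permutation test for equality of correlated AUCs

def permutation_auc_spread_p(score_sets, labels, n_perm=2000, seed=0) -> float:
    """Permutation p-value for the null that all k curves discriminate
    equally.

    Scores are rank-transformed per curve (AUC is rank-based), then the
    curve assignment is shuffled independently within each participant;
    the statistic is the spread (max - min) of the k pair-count AUCs.
    """
    from scipy.stats import rankdata

    matrix = np.vstack([rankdata(s) for s in score_sets])
    k, n = matrix.shape
    y = np.asarray(labels)
    y = y.astype(bool) if y.dtype.kind in "bif" else (y == "decline")

    def spread(m):
        aucs = [pair_count_auc(m[r], y) for r in range(k)]
        return max(aucs) - min(aucs)

    observed = spread(matrix)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = matrix.copy()
        for j in range(n):
            perm[:, j] = perm[rng.permutation(k), j]
        if spread(perm) >= observed - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)
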