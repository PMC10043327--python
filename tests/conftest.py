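"""Shared fixtures and independent reference implementations (oracles).

The oracles here are deliberately naive pure-Python implementations, kept
separate from the package's vectorized code paths so equivalence tests
carry evidential weight.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest

from mdrscan.genotype_io import GenotypeMatrix, VariantRecord
from mdrscan.network_panel import SnpPanel


def make_matrix(dosage: np.ndarray, chrom: str = "1") -> GenotypeMatrix:
    """Wrap a plain dosage array in a GenotypeMatrix with stub metadata."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    variants = [
        VariantRecord(f"rs{j:04d}", chrom, 1000 * (j + 1), "A", "G") for j in range(m)
    ]
    return GenotypeMatrix([f"S{i:04d}" for i in range(n)], variants, dosage)


def make_panel(matrix: GenotypeMatrix, name: str = "net") -> SnpPanel:
    return SnpPanel(name, matrix.snp_ids, {s: [] for s in matrix.snp_ids})


def hwe_enumeration_oracle(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact-rational enumeration of the heterozygote-count distribution.

    P(n_het | n, n_rare) proportional to n! / (hom_r! het! hom_c!) * 2^het;
    sums the probabilities of all outcomes no more probable than observed.
    """
    n = n_AA + n_Aa + n_aa
    n_rare = 2 * min(n_AA, n_aa) + n_Aa
    weights = {}
    for het in range(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2):
        hom_r = (n_rare - het) // 2
        hom_c = n - het - hom_r
        w = Fraction(2**het)
        # multinomial n! / (hom_r! het! hom_c!) via integer binomials
        w *= comb(n, het) * comb(n - het, hom_r)
        weights[het] = w
    total = sum(weights.values())
    obs = weights[n_Aa]
    p = sum(w for w in weights.values() if w <= obs)
    return float(Fraction(p, total))


def brute_force_search(matrix, scores, k, fold, threshold=0.0):
    """Naive fold-wise exhaustive search: dict-based cells, loop per combo.

    Returns (winner combos per fold, test BA per fold) under the same fold
    labels a SearchConfig-driven search would use.
    """
    snp_ids = matrix.snp_ids
    s = scores.scores
    n_folds = fold.max() + 1
    winners, test_bas = [], []
    for f in range(n_folds):
        train = np.flatnonzero(fold != f)
        test = np.flatnonzero(fold == f)
        best_combo, best_ba = None, -np.inf
        for combo in combinations(snp_ids, k):
            sums: dict[tuple, float] = {}
            for i in train:
                cell = tuple(int(matrix.column(snp)[i]) for snp in combo)
                sums[cell] = sums.get(cell, 0.0) + s[i]
            high = {c for c, v in sums.items() if v > threshold + 1e-9}
            tp = fn = tn = fp = 0
            for i in train:
                cell = tuple(int(matrix.column(snp)[i]) for snp in combo)
                pred, truth = cell in high, s[i] > 0
                tp += pred and truth
                fn += (not pred) and truth
                tn += (not pred) and (not truth)
                fp += pred and (not truth)
            ba = 0.5 * (tp / (tp + fn) + tn / (tn + fp))
            if ba > best_ba:  # first max wins: combinations() is lexicographic
                best_ba, best_combo = ba, combo
        tp = fn = tn = fp = 0
        sums = {}
        for i in train:
            cell = tuple(int(matrix.column(snp)[i]) for snp in best_combo)
            sums[cell] = sums.get(cell, 0.0) + s[i]
        high = {c for c, v in sums.items() if v > threshold + 1e-9}
        for i in test:
            cell = tuple(int(matrix.column(snp)[i]) for snp in best_combo)
            pred, truth = cell in high, s[i] > 0
            tp += pred and truth
            fn += (not pred) and truth
            tn += (not pred) and (not truth)
            fp += pred and (not truth)
        ba = 0.5 * (tp / (tp + fn) + tn / (tn + fp)) if (tp + fn) and (tn + fp) else np.nan
        winners.append(best_combo)
        test_bas.append(ba)
    return winners, test_bas


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def toy_samples():
    """Small sample table with non-collinear covariates and both classes."""
    r = np.random.default_rng(7)
    n = 60
    return pd.DataFrame(
        {
            "sample_id": [f"S{i:04d}" for i in range(n)],
            "status5y": r.binomial(1, 0.3, n),
            "stage": r.choice(["I", "II", "III"], n),
            "location": r.choice(["colon", "rectum"], n),
            "chemo": r.binomial(1, 0.6, n),
            "radio": r.binomial(1, 0.3, n),
        }
    )
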