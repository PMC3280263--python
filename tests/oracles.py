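"""Independent first-principles oracles used to cross-check the package.

Everything here is deliberately naive: dictionaries, exact rational
arithmetic, per-subject loops, and a hand-rolled Newton logistic fitter.
None of it shares code with the implementation under test.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np


def brute_cells(values, pheno, combo):
    """Per-cell [cases, controls] via a plain subject loop."""
    cells: dict[tuple, list[int]] = {}
    for row, y in zip(values, pheno):
        key = tuple(int(row[a]) for a in combo)
        cnt = cells.setdefault(key, [0, 0])
        cnt[0 if y == 1 else 1] += 1
    return cells


def brute_labels(cells, n_cases, n_controls, tie="strict"):
    """High/low per realised cell against T = cases/controls, in exact
    rational arithmetic (a cell with no controls but cases has ratio +inf)."""
    T = Fraction(n_cases, n_controls)
    labels = {}
    for key, (case, ctrl) in cells.items():
        if ctrl == 0:
            high = case > 0
        else:
            ratio = Fraction(case, ctrl)
            high = ratio > T if tie == "strict" else ratio >= T
        labels[key] = "high" if high else "low"
    return labels


def brute_confusion(labels, values, pheno, combo):
    """Classify every subject; unseen cells are low (default policy)."""
    tp = fp = tn = fn = 0
    for row, y in zip(values, pheno):
        key = tuple(int(row[a]) for a in combo)
        high = labels.get(key, "low") == "high"
        if high and y == 1:
            tp += 1
        elif high:
            fp += 1
        elif y == 1:
            fn += 1
        else:
            tn += 1
    return tp, fp, tn, fn


def brute_balanced_accuracy(tp, fp, tn, fn):
    return 0.5 * (tp / (tp + fn) + tn / (tn + fp))


def brute_fold_scores(values, pheno, combo, fold_of_subject, n_folds):
    """Per-fold (train_ba, test_ba, integer winner score) from scratch."""
    out = []
    for f in range(n_folds):
        tr = [i for i in range(len(pheno)) if fold_of_subject[i] != f]
        te = [i for i in range(len(pheno)) if fold_of_subject[i] == f]
        v_tr, p_tr = values[tr], pheno[tr]
        cells = brute_cells(v_tr, p_tr, combo)
        cas = int(p_tr.sum())
        ctr = len(tr) - cas
        labels = brute_labels(cells, cas, ctr)
        tp, fp, tn, fn = brute_confusion(labels, v_tr, p_tr, combo)
        train_ba = brute_balanced_accuracy(tp, fp, tn, fn)
        score = tp * ctr + tn * cas
        tp2, fp2, tn2, fn2 = brute_confusion(labels, values[te], pheno[te], combo)
        test_ba = brute_balanced_accuracy(tp2, fp2, tn2, fn2)
        out.append((train_ba, test_ba, score))
    return out


def pearson_2x2(a, b, c, d):
    """Textbook Pearson chi-square for the table [[a, b], [c, d]]."""
    n = a + b + c + d
    num = n * (a * d - b * c) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    return num / den


def newton_logistic(X, y, max_iter=100, tol=1e-12):
    """Newton-Raphson logistic regression; returns the log-likelihood."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1 - mu)
        grad = X.T @ (y - mu)
        hess = (X * W[:, None]).T @ X
        step = np.linalg.solve(hess + 1e-12 * np.eye(X.shape[1]), grad)
        beta = beta + step
        if np.abs(step).max() < tol:
            break
    eta = X @ beta
    mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
    return float((y * np.log(mu) + (1 - y) * np.log(1 - mu)).sum())
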