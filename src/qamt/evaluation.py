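"""Fidelity, utility and privacy metrics for generated medical time-series.

Static-event fidelity uses patient-level n-gram probabilities (unigram,
bigram, trigram within a visit; sequential bigram across consecutive visits)
compared by Pearson correlation over the top-1000 real-data n-grams.
Temporal fidelity embeds each patient as per-variable (min, max, mean, std)
over the first 48 h and computes manifold precision/recall/density/coverage
(PRDC) plus the mean squared difference between inter-variable correlation
matrices (MSEcorr).  Privacy is audited with a nearest-neighbor membership
inference attack: member and holdout nearest-to-synthetic distance samples
are fitted with Gaussians and compared by Wasserstein distance,
Jensen-Shannon divergence and the AUROC of the distance-threshold attack.

Conventions: standard deviations are population (ddof=0) throughout; n-gram
probability is the number of patients exhibiting the n-gram divided by the
total number of patients; Hamming distance between unequal-length event
sequences pads with a null symbol and normalizes by the padded length.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sstats
from scipy.spatial.distance import cdist
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from .data_model import Dataset, PatientRecord

logger = logging.getLogger(__name__)

NGRAM_KINDS = ("unigram", "bigram", "trigram", "sequential_bigram")
_WITHIN = {"unigram": 1, "bigram": 2, "trigram": 3}


# ---------------------------------------------------------------------------
# n-gram fidelity

@dataclass
class NgramTable:
    kind: str
    probs: dict[tuple[str, ...], float]
    n_patients: int


def _patient_ngrams(p: PatientRecord, kind: str) -> set[tuple[str, ...]]:
    grams: set[tuple[str, ...]] = set()
    if kind in _WITHIN:
        n = _WITHIN[kind]
        for v in p.visits:
            codes = [e.code for e in v.static.events]
            for i in range(len(codes) - n + 1):
                grams.add(tuple(codes[i:i + n]))
    elif kind == "sequential_bigram":
        for va, vb in zip(p.visits, p.visits[1:]):
            ea, eb = va.static.events, vb.static.events
            if ea and eb:
                grams.add((ea[-1].code, eb[0].code))
    else:
        raise ValueError(f"unknown n-gram kind {kind!r}")
    return grams


def ngram_probs(d: Dataset, kind: str) -> NgramTable:
    """Patient-level n-gram probability: frequency of patients exhibiting the
    n-gram divided by the total number of patients."""
    counts: dict[tuple[str, ...], int] = {}
    for p in d.patients:
        for gram in _patient_ngrams(p, kind):
            counts[gram] = counts.get(gram, 0) + 1
    n = max(len(d.patients), 1)
    return NgramTable(kind=kind, probs={g: c / n for g, c in counts.items()},
                      n_patients=len(d.patients))


@dataclass(frozen=True)
class NgramCorrelation:
    r: Optional[float]
    reason: Optional[str] = None


def ngram_correlation(real: NgramTable, gen: NgramTable,
                      top: int = 1000) -> NgramCorrelation:
    """Pearson r between the top-``top`` real-data n-gram probabilities and
    the aligned generated probabilities (absent n-grams contribute 0)."""
    if real.kind != gen.kind:
        raise ValueError(f"kind mismatch: {real.kind} vs {gen.kind}")
    if not real.probs:
        return NgramCorrelation(None, "real table is empty")
    ranked = sorted(real.probs.items(), key=lambda kv: (-kv[1], kv[0]))[:top]
    x = np.array([p for _, p in ranked])
    y = np.array([gen.probs.get(g, 0.0) for g, _ in ranked])
    if len(x) < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return NgramCorrelation(None, "fewer than 2 distinct values on one side")
    return NgramCorrelation(float(sstats.pearsonr(x, y)[0]))


# ---------------------------------------------------------------------------
# temporal embeddings

@dataclass
class EmbeddingMatrix:
    values: np.ndarray  # (n_patients, 4 * n_variables)
    columns: list[str]
    patients: list[str]
    imputed_columns: list[str] = field(default_factory=list)


def temporal_embeddings(d: Dataset, window: int = 48,
                        variables: Optional[Sequence[str]] = None) -> EmbeddingMatrix:
    """Per patient, per variable: (min, max, mean, population std) over
    measurements with time < ``window`` hours in the first visit; variables
    unobserved for a patient are column-median imputed (logged)."""
    if variables is None:
        variables = d.schema.get("variables") or sorted({
            name for p in d.patients for v in p.visits
            for pt in v.temporal.points for name, _ in pt.measurements})
    variables = list(variables)
    stats_names = ("min", "max", "mean", "std")
    columns = [f"{v}_{s}" for v in variables for s in stats_names]
    rows = np.full((len(d.patients), len(columns)), np.nan)
    for i, p in enumerate(d.patients):
        by_var: dict[str, list[float]] = {}
        if p.visits:
            for pt in p.visits[0].temporal.points:
                if pt.time < window:
                    for name, value in pt.measurements:
                        by_var.setdefault(name, []).append(value)
        for j, var in enumerate(variables):
            vals = by_var.get(var)
            if vals:
                a = np.asarray(vals)
                rows[i, 4 * j:4 * j + 4] = (a.min(), a.max(), a.mean(), a.std(ddof=0))
    imputed = []
    for col in range(rows.shape[1]):
        missing = np.isnan(rows[:, col])
        if missing.any():
            med = np.nanmedian(rows[:, col]) if not missing.all() else 0.0
            rows[missing, col] = med
            imputed.append(columns[col])
    if imputed:
        logger.info("temporal_embeddings: median-imputed columns %s", imputed)
    return EmbeddingMatrix(values=rows, columns=columns,
                           patients=[p.patient_id for p in d.patients],
                           imputed_columns=imputed)


# ---------------------------------------------------------------------------
# PRDC

@dataclass(frozen=True)
class PRDC:
    precision: float
    recall: float
    density: float
    coverage: float


def prdc(real: EmbeddingMatrix, gen: EmbeddingMatrix, k: int = 5,
         standardize: bool = True) -> PRDC:
    """Manifold precision/recall/density/coverage with k-NN radii on
    Euclidean distances (radius = distance to the k-th nearest within-set
    neighbor, self excluded)."""
    x, y = np.asarray(real.values, float), np.asarray(gen.values, float)
    if len(x) <= k or len(y) <= k:
        raise ValueError(f"PRDC needs more than k={k} rows on each side")
    if standardize:
        mu, sd = x.mean(axis=0), x.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        x, y = (x - mu) / sd, (y - mu) / sd
    d_xx = cdist(x, x)
    d_yy = cdist(y, y)
    d_xy = cdist(x, y)  # real rows x gen columns
    rad_x = np.sort(d_xx, axis=1)[:, k]  # column 0 is self (distance 0)
    rad_y = np.sort(d_yy, axis=1)[:, k]
    within_real = d_xy <= rad_x[:, None]           # gen j inside real i's ball
    precision = float(within_real.any(axis=0).mean())
    recall = float((d_xy.T <= rad_y[:, None]).any(axis=0).mean())
    density = float(within_real.sum() / (k * len(y)))
    coverage = float((d_xy.min(axis=1) <= rad_x).mean())
    return PRDC(precision, recall, density, coverage)


# ---------------------------------------------------------------------------
# correlation-matrix MSE

def _value_frame(d: Dataset, variables: Optional[Sequence[str]] = None) -> pd.DataFrame:
    if variables is None:
        variables = d.schema.get("variables") or sorted({
            name for p in d.patients for v in p.visits
            for pt in v.temporal.points for name, _ in pt.measurements})
    rows = []
    for p in d.patients:
        for v in p.visits:
            for pt in v.temporal.points:
                row = dict.fromkeys(variables, np.nan)
                for name, value in pt.measurements:
                    if name in row:
                        row[name] = value
                rows.append(row)
    return pd.DataFrame(rows, columns=list(variables))


def msecorr(real: Union[Dataset, np.ndarray], gen: Union[Dataset, np.ndarray],
            variables: Optional[Sequence[str]] = None) -> float:
    """Mean squared difference between the two pairwise-complete Pearson
    correlation matrices, averaged over the upper triangle."""
    def corr(side):
        if isinstance(side, Dataset):
            return _value_frame(side, variables).corr().to_numpy()
        return pd.DataFrame(np.asarray(side, float)).corr().to_numpy()
    c_real, c_gen = corr(real), corr(gen)
    if c_real.shape != c_gen.shape:
        raise ValueError("variable sets differ between the two sides")
    iu = np.triu_indices_from(c_real, k=1)
    diff = c_real[iu] - c_gen[iu]
    diff = diff[np.isfinite(diff)]
    return float(np.mean(diff ** 2)) if diff.size else 0.0


# ---------------------------------------------------------------------------
# membership inference privacy

@dataclass(frozen=True)
class PrivacyReport:
    side: str
    wd: float
    jsd: float
    auroc: float
    n_member: int
    n_holdout: int


_NULL = "\x00"


def hamming_event_distance(a: Sequence[str], b: Sequence[str]) -> float:
    """Normalized Hamming distance between event-code sequences, null-padded
    to equal length."""
    n = max(len(a), len(b))
    if n == 0:
        return 0.0
    pa = list(a) + [_NULL] * (n - len(a))
    pb = list(b) + [_NULL] * (n - len(b))
    return sum(x != y for x, y in zip(pa, pb)) / n


def _event_sequences(d: Dataset) -> list[list[str]]:
    return [[e.code for v in p.visits for e in v.static.events] for p in d.patients]


def _gaussian_wd(mu1, sd1, mu2, sd2) -> float:
    # closed-form 2-Wasserstein between 1-D Gaussians
    return float(np.sqrt((mu1 - mu2) ** 2 + (sd1 - sd2) ** 2))


def _gaussian_jsd(mu1, sd1, mu2, sd2, grid_size: int = 2001) -> float:
    if abs(mu1 - mu2) < 1e-15 and abs(sd1 - sd2) < 1e-15:
        return 0.0
    sd1, sd2 = max(sd1, 1e-9), max(sd2, 1e-9)
    lo = min(mu1 - 6 * sd1, mu2 - 6 * sd2)
    hi = max(mu1 + 6 * sd1, mu2 + 6 * sd2)
    # keep each density representable on the grid (degenerate sd -> one cell)
    cell = (hi - lo) / (grid_size - 1)
    sd1, sd2 = max(sd1, cell), max(sd2, cell)
    xs = np.linspace(lo, hi, grid_size)
    p = sstats.norm.pdf(xs, mu1, sd1)
    q = sstats.norm.pdf(xs, mu2, sd2)
    p, q = p / p.sum(), q / q.sum()
    m = 0.5 * (p + q)

    def kl(a, b):
        mask = a > 0
        return float(np.sum(a[mask] * np.log(a[mask] / b[mask])))
    return 0.5 * kl(p, m) + 0.5 * kl(q, m)


def mia_privacy(real: Dataset, gen: Dataset, side: str = "temporal",
                member_count: Optional[int] = None) -> PrivacyReport:
    """Nearest-neighbor membership inference audit.

    The first ``member_count`` real patients (default: half) play the member
    role, the rest the holdout role.  Each real patient's nearest-neighbor
    distance to the generated set is computed (Hamming over event sequences
    for the static side, Euclidean over first-48-h embeddings for the
    temporal side); Gaussians fitted to the member and holdout distance
    samples are compared by closed-form Wasserstein distance and numeric
    Jensen-Shannon divergence, and AUROC scores the distance-threshold attack.
    """
    n = len(real.patients)
    if n < 4:
        raise ValueError("mia_privacy needs at least 4 real patients")
    m = member_count if member_count is not None else n // 2
    if side == "static":
        seqs = _event_sequences(real)
        gen_seqs = _event_sequences(gen)
        dists = np.array([
            min(hamming_event_distance(s, t) for t in gen_seqs) for s in seqs])
    elif side == "temporal":
        variables = real.schema.get("variables") or None
        emb_r = temporal_embeddings(real, variables=variables)
        emb_g = temporal_embeddings(gen, variables=variables)
        dists = cdist(emb_r.values, emb_g.values).min(axis=1)
    else:
        raise ValueError(f"unknown side {side!r}")
    member, holdout = dists[:m], dists[m:]
    mu1, sd1 = float(member.mean()), float(member.std(ddof=0))
    mu2, sd2 = float(holdout.mean()), float(holdout.std(ddof=0))
    labels = np.concatenate([np.ones(len(member)), np.zeros(len(holdout))])
    scores = -np.concatenate([member, holdout])  # members expected closer if leaked
    if np.ptp(scores) == 0:
        auroc = 0.5
    else:
        auroc = float(roc_auc_score(labels, scores))
    return PrivacyReport(side=side, wd=_gaussian_wd(mu1, sd1, mu2, sd2),
                         jsd=_gaussian_jsd(mu1, sd1, mu2, sd2), auroc=auroc,
                         n_member=len(member), n_holdout=len(holdout))


# ---------------------------------------------------------------------------
# generic utility harness (train on synthetic, test on real)

@dataclass
class TSTRTask:
    """Pluggable downstream task: a label and a feature map per record."""

    label: Callable[[PatientRecord], object]
    features: Callable[[PatientRecord], np.ndarray]
    name: str = "task"


def _xy(d: Dataset, task: TSTRTask) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([task.features(p) for p in d.patients])
    y = np.array([task.label(p) for p in d.patients])
    return x, y


def _fit_score(x_tr, y_tr, x_te, y_te, seed: int) -> float:
    if len(set(y_tr.tolist())) < 2:
        majority = y_tr[0]
        return float(np.mean(y_te == majority))
    clf = LogisticRegression(max_iter=2000, random_state=seed)
    clf.fit(x_tr, y_tr)
    return float(clf.score(x_te, y_te))


def utility_tstr(real: Dataset, gen: Dataset, task: TSTRTask,
                 seed: int = 0) -> dict[str, float]:
    """Accuracy of a ridge-regularized linear classifier trained on one side
    and tested on the other, both directions, plus their difference."""
    x_r, y_r = _xy(real, task)
    x_g, y_g = _xy(gen, task)
    tstr = _fit_score(x_g, y_g, x_r, y_r, seed)
    trts = _fit_score(x_r, y_r, x_g, y_g, seed)
    return {"train_gen_test_real": tstr, "train_real_test_gen": trts,
            "difference": tstr - trts}


# ---------------------------------------------------------------------------
# noise-robustness harness

def _dataset_variable_stds(d: Dataset) -> dict[str, float]:
    by_var: dict[str, list[float]] = {}
    for p in d.patients:
        for v in p.visits:
            for pt in v.temporal.points:
                for name, value in pt.measurements:
                    by_var.setdefault(name, []).append(value)
    return {name: float(np.std(vals)) for name, vals in by_var.items()}


def inject_noise(d: Dataset, level: float, seed: int = 0,
                 ) -> tuple[Dataset, dict[str, float]]:
    """Add zero-mean Gaussian noise with std = level x per-variable std;
    returns the noisy copy and the achieved per-variable injected-noise std."""
    stds = _dataset_variable_stds(d)
    noisy = copy.deepcopy(d)
    rng = np.random.default_rng(seed)
    injected: dict[str, list[float]] = {name: [] for name in stds}
    for p in noisy.patients:
        for v in p.visits:
            for pt in v.temporal.points:
                new = []
                for name, value in pt.measurements:
                    eps = float(rng.normal(0.0, level * stds.get(name, 0.0))) if level > 0 else 0.0
                    injected.setdefault(name, []).append(eps)
                    new.append((name, value + eps))
                pt.measurements = new
    achieved = {name: float(np.std(vals)) if vals else 0.0
                for name, vals in injected.items()}
    return noisy, achieved


def noise_harness(d: Dataset, levels: Sequence[float], seed: int = 0,
                  k: int = 5) -> tuple[pd.DataFrame, dict[float, dict[str, float]]]:
    """Fidelity metrics of noise-perturbed data against the original, one row
    per level; also returns achieved injected-noise stds for calibration."""
    if any(not (0 <= l <= 1) for l in levels):
        raise ValueError("levels must lie in [0, 1]")
    variables = d.schema.get("variables") or None
    emb_base = temporal_embeddings(d, variables=variables)
    rows = []
    achieved_all: dict[float, dict[str, float]] = {}
    for i, level in enumerate(levels):
        noisy, achieved = inject_noise(d, level, seed=seed + i)
        achieved_all[level] = achieved
        emb_noisy = temporal_embeddings(noisy, variables=variables)
        p = prdc(emb_base, emb_noisy, k=k)
        rows.append({
            "level": level,
            "precision": p.precision, "recall": p.recall,
            "density": p.density, "coverage": p.coverage,
            "msecorr": msecorr(d, noisy, variables=variables),
        })
    return pd.DataFrame(rows), achieved_all
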