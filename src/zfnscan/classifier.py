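"""Position-wise Naive Bayes classifier over fixed-length DNA windows.

The model assumes positions are independent given the class.  For class
``c`` with ``n_c`` training windows and Laplace pseudocount ``alpha``::

    P(base b at position p | c) = (count_{p,b,c} + alpha) / (n_c + 4 alpha)

Scores are reported as the posterior probability of the *inactive* class,
so the scale runs 0 -> 1 with **lower scores meaning a higher probability
that the site is cleaved** — the orientation used for all downstream
binning and genome-wide ranking.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from ._dna import encode, encode_strict

FORMAT_VERSION = 1


def _features(w) -> str:
    return w if isinstance(w, str) else w.features


@dataclass
class NaiveBayesModel:
    """Per-position nucleotide log-likelihoods for the active/inactive classes."""

    log_lik_active: np.ndarray  # (window_length, 4)
    log_lik_inactive: np.ndarray  # (window_length, 4)
    log_prior: np.ndarray  # (2,) in order (active, inactive)
    pseudocount: float

    def __post_init__(self):
        la, li = np.asarray(self.log_lik_active), np.asarray(self.log_lik_inactive)
        if la.shape != li.shape or la.ndim != 2 or la.shape[1] != 4:
            raise ValueError("likelihood tables must both be (window_length, 4)")
        for name, table in (("active", la), ("inactive", li)):
            sums = np.exp(table).sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-12):
                raise ValueError(f"{name} likelihoods do not sum to 1 per position")
        if not np.isclose(np.exp(self.log_prior).sum(), 1.0, atol=1e-12):
            raise ValueError("class priors do not sum to 1")

    @property
    def window_length(self) -> int:
        return self.log_lik_active.shape[0]

    def score(self, window: str) -> float:
        """P(inactive | window) in [0, 1]; lower = more likely cleaved."""
        codes = encode_strict(window)
        if codes.shape[0] != self.window_length:
            raise ValueError(
                f"window length {codes.shape[0]} != model window length {self.window_length}"
            )
        return float(self.score_encoded(codes[None, :])[0])

    def score_encoded(self, mat: np.ndarray) -> np.ndarray:
        """Vectorized scoring of an (n, window_length) uint8 code matrix."""
        pos = np.arange(self.window_length)
        la = self.log_prior[0] + self.log_lik_active[pos, mat].sum(axis=1)
        li = self.log_prior[1] + self.log_lik_inactive[pos, mat].sum(axis=1)
        norm = np.logaddexp(la, li)
        return np.exp(li - norm)

    def score_many(self, windows) -> np.ndarray:
        mat = np.stack([encode(_features(w)) for w in windows])
        if (mat >= 4).any():
            raise ValueError("ambiguity code in window")
        if mat.shape[1] != self.window_length:
            raise ValueError("window length mismatch")
        return self.score_encoded(mat)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "format_version": FORMAT_VERSION,
            "model": "position-wise-naive-bayes",
            "window_length": self.window_length,
            "pseudocount": self.pseudocount,
            "prior": {"active": float(np.exp(self.log_prior[0])), "inactive": float(np.exp(self.log_prior[1]))},
            "prob": {
                "active": np.exp(self.log_lik_active).tolist(),
                "inactive": np.exp(self.log_lik_inactive).tolist(),
            },
        }

    def to_json(self, path: str | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            from .io import atomic_write

            with atomic_write(path) as out:
                out.write(text + "\n")
        return text

    @classmethod
    def from_dict(cls, data: dict) -> "NaiveBayesModel":
        if data.get("format_version") != FORMAT_VERSION:
            raise ValueError(f"unsupported model format_version {data.get('format_version')!r}")
        return cls(
            log_lik_active=np.log(np.asarray(data["prob"]["active"], dtype=float)),
            log_lik_inactive=np.log(np.asarray(data["prob"]["inactive"], dtype=float)),
            log_prior=np.log(np.array([data["prior"]["active"], data["prior"]["inactive"]], dtype=float)),
            pseudocount=float(data["pseudocount"]),
        )

    @classmethod
    def from_json(cls, path: str) -> "NaiveBayesModel":
        with open(path) as handle:
            return cls.from_dict(json.load(handle))


def _count_matrix(windows, window_length: int) -> np.ndarray:
    counts = np.zeros((window_length, 4), dtype=np.int64)
    for w in windows:
        codes = encode_strict(_features(w))
        if codes.shape[0] != window_length:
            raise ValueError("all windows must share one length")
        counts[np.arange(window_length), codes] += 1
    return counts


def train_from_counts(
    counts_active: np.ndarray,
    n_active: int,
    counts_inactive: np.ndarray,
    n_inactive: int,
    pseudocount: float = 1.0,
    priors: str = "uniform",
) -> NaiveBayesModel:
    """Build a model directly from per-position nucleotide count tables."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if n_active <= 0 or n_inactive <= 0:
        raise ValueError("both classes must be non-empty")
    log_lik_a = np.log(counts_active + pseudocount) - np.log(n_active + 4.0 * pseudocount)
    log_lik_i = np.log(counts_inactive + pseudocount) - np.log(n_inactive + 4.0 * pseudocount)
    if priors == "uniform":
        prior = np.array([0.5, 0.5])
    elif priors == "empirical":
        total = n_active + n_inactive
        prior = np.array([n_active / total, n_inactive / total])
    else:
        raise ValueError("priors must be 'uniform' or 'empirical'")
    return NaiveBayesModel(log_lik_a, log_lik_i, np.log(prior), pseudocount)


def train(active, inactive, pseudocount: float = 1.0, priors: str = "uniform") -> NaiveBayesModel:
    """Train on labeled windows (strings or objects with ``.features``)."""
    active, inactive = list(active), list(inactive)
    if not active or not inactive:
        raise ValueError("both classes must be non-empty")
    window_length = len(_features(active[0]))
    counts_a = _count_matrix(active, window_length)
    counts_i = _count_matrix(inactive, window_length)
    return train_from_counts(counts_a, len(active), counts_i, len(inactive), pseudocount, priors)


@dataclass
class CVReport:
    """Stratified k-fold cross-validation metrics (active = positive class)."""

    k: int
    seed: int
    accuracy: list = field(default_factory=list)
    sensitivity: list = field(default_factory=list)
    specificity: list = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracy))

    @property
    def mean_sensitivity(self) -> float:
        return float(np.mean(self.sensitivity))

    @property
    def mean_specificity(self) -> float:
        return float(np.mean(self.specificity))

    def to_json(self) -> str:
        return json.dumps(
            {
                "k": self.k,
                "seed": self.seed,
                "folds": [
                    {"accuracy": a, "sensitivity": s, "specificity": p}
                    for a, s, p in zip(self.accuracy, self.sensitivity, self.specificity)
                ],
                "mean_accuracy": self.mean_accuracy,
                "mean_sensitivity": self.mean_sensitivity,
                "mean_specificity": self.mean_specificity,
            },
            indent=1,
        )


def cross_validate(
    active,
    inactive,
    k: int = 10,
    seed: int = 0,
    pseudocount: float = 1.0,
    priors: str = "uniform",
) -> CVReport:
    """Stratified k-fold CV; the model is retrained on training folds only and
    windows are classified active when score < 0.5."""
    active, inactive = list(active), list(inactive)
    if len(active) < k or len(inactive) < k:
        raise ValueError(
            f"each class needs >= k members for stratified {k}-fold CV "
            f"(got {len(active)} active, {len(inactive)} inactive); use a smaller k"
        )
    windows = active + inactive
    y = np.array([1] * len(active) + [0] * len(inactive))
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    report = CVReport(k=k, seed=seed)
    for train_idx, test_idx in skf.split(np.zeros(len(y)), y):
        model = train(
            [windows[i] for i in train_idx if y[i] == 1],
            [windows[i] for i in train_idx if y[i] == 0],
            pseudocount=pseudocount,
            priors=priors,
        )
        scores = model.score_many([windows[i] for i in test_idx])
        pred_active = scores < 0.5
        truth_active = y[test_idx] == 1
        tp = int(np.sum(pred_active & truth_active))
        tn = int(np.sum(~pred_active & ~truth_active))
        fp = int(np.sum(pred_active & ~truth_active))
        fn = int(np.sum(~pred_active & truth_active))
        report.accuracy.append((tp + tn) / len(test_idx))
        report.sensitivity.append(tp / (tp + fn) if tp + fn else float("nan"))
        report.specificity.append(tn / (tn + fp) if tn + fp else float("nan"))
    return report
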