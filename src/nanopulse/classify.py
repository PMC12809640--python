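"""Naive Bayes classification of resistive pulses.

The feature is the per-sample fractional blockade ``|I - I0| / |I0|`` within
an event, treated as conditionally i.i.d. given the class (the naive
assumption). Class-conditional densities come either from labeled training
events (fixed-bin histogram with add-one smoothing) or from the theoretical
tumbling-ellipsoid density of a protein spec (physics-driven training). An
event's score is the log prior plus the summed per-sample log densities;
the argmax wins, ties broken to the lexicographically smallest label.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np

from .shape import intraevent_pdf

UNCLASSIFIABLE = "__unclassifiable__"


@dataclass
class _ClassDensity:
    edges: np.ndarray  # bin edges over fractional blockade
    log_density: np.ndarray  # per-bin log density (integrates to ~1)

    def logpdf(self, f: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.edges, f, side="right") - 1
        out = np.full(f.shape, -np.inf)
        ok = (idx >= 0) & (idx < self.log_density.size)
        out[ok] = self.log_density[idx[ok]]
        return out


class BlockadeNBC:
    """Naive Bayes classifier over per-sample fractional blockades.

    fit/predict-style interface: train with :meth:`fit` (labeled events) or
    :meth:`fit_theoretical` (protein specs), classify single events with
    :meth:`classify` or lists with :meth:`predict`.
    """

    def __init__(self, n_bins: int = 200, edge_pad: int = 3) -> None:
        self.n_bins = n_bins
        self.edge_pad = edge_pad
        self.classes_: List[str] = []
        self.log_prior_: Dict[str, float] = {}
        self.densities_: Dict[str, _ClassDensity] = {}

    # -- features -----------------------------------------------------------

    def _features(self, samples: np.ndarray, i0: float) -> np.ndarray:
        s = np.asarray(samples, dtype=float)
        core = s[self.edge_pad : s.size - self.edge_pad]
        if core.size == 0:
            core = s
        return np.abs(core - i0) / abs(i0)

    # -- training -----------------------------------------------------------

    def fit(
        self,
        events_by_class: Mapping[str, Sequence],
        baselines: Optional[Mapping[str, float]] = None,
        priors: Optional[Mapping[str, float]] = None,
    ) -> "BlockadeNBC":
        """Train from labeled events.

        ``events_by_class`` maps label -> sequence of EventRecord (their
        ``baseline_pA`` is used as I0 unless ``baselines`` overrides it).
        """
        if not events_by_class:
            raise ValueError("at least one class is required")
        feats: Dict[str, np.ndarray] = {}
        for label, events in events_by_class.items():
            if len(events) == 0:
                raise ValueError(f"class {label!r} has no training events")
            fs = []
            for ev in events:
                i0 = baselines[label] if baselines else ev.baseline_pA
                fs.append(self._features(ev.samples, i0))
            feats[label] = np.concatenate(fs)
        all_f = np.concatenate(list(feats.values()))
        lo, hi = float(np.min(all_f)), float(np.max(all_f))
        span = max(hi - lo, 1e-12)
        edges = np.linspace(lo - 0.02 * span, hi + 0.02 * span, self.n_bins + 1)
        width = edges[1] - edges[0]
        self.classes_ = sorted(feats)
        self.densities_ = {}
        for label in self.classes_:
            counts, _ = np.histogram(feats[label], bins=edges)
            smoothed = counts + 1.0  # add-one: no -inf log likelihoods
            dens = smoothed / (smoothed.sum() * width)
            self.densities_[label] = _ClassDensity(edges, np.log(dens))
        self._set_priors(priors)
        return self

    def fit_theoretical(
        self,
        specs: Mapping[str, tuple],
        pore,
        i0: float,
        noise_sd: float,
        priors: Optional[Mapping[str, float]] = None,
    ) -> "BlockadeNBC":
        """Train from physics: ``specs`` maps label -> (m, volume_nm3)."""
        if not specs:
            raise ValueError("at least one class is required")
        self.classes_ = sorted(specs)
        self.densities_ = {}
        for label in self.classes_:
            m, vol = specs[label]
            grid, pdf = intraevent_pdf(m, vol, pore, i0, noise_sd)
            f_grid = grid / abs(i0)
            edges = np.concatenate(
                [f_grid - 0.5 * (f_grid[1] - f_grid[0]),
                 [f_grid[-1] + 0.5 * (f_grid[1] - f_grid[0])]]
            )
            dens = np.maximum(pdf * abs(i0), 1e-300)
            width = edges[1] - edges[0]
            dens = dens / (dens.sum() * width)
            self.densities_[label] = _ClassDensity(edges, np.log(dens))
        self._set_priors(priors)
        return self

    def _set_priors(self, priors: Optional[Mapping[str, float]]) -> None:
        if priors is None:
            p = {c: 1.0 / len(self.classes_) for c in self.classes_}
        else:
            tot = sum(priors[c] for c in self.classes_)
            p = {c: priors[c] / tot for c in self.classes_}
        self.log_prior_ = {c: float(np.log(v)) for c, v in p.items()}

    # -- inference ----------------------------------------------------------

    def classify(self, event, i0: Optional[float] = None) -> tuple[str, Dict[str, float]]:
        """Label one event; returns (label, per-class log posterior scores)."""
        if not self.classes_:
            raise ValueError("classifier is not trained")
        i0 = event.baseline_pA if i0 is None else i0
        f = self._features(event.samples, i0)
        if f.size == 0:
            raise ValueError("event has no intraevent samples")
        scores = {
            c: self.log_prior_[c] + float(np.sum(self.densities_[c].logpdf(f)))
            for c in self.classes_
        }
        if all(not np.isfinite(v) for v in scores.values()):
            return UNCLASSIFIABLE, scores
        # ties break to the lexicographically smallest label
        top = max(scores.values())
        winners = sorted(c for c, v in scores.items() if v == top)
        return winners[0], scores

    def predict(self, events: Sequence, i0: Optional[float] = None) -> List[str]:
        return [self.classify(ev, i0)[0] for ev in events]

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_bins": self.n_bins,
                "edge_pad": self.edge_pad,
                "classes": self.classes_,
                "log_prior": self.log_prior_,
                "densities": {
                    c: {
                        "edges": self.densities_[c].edges.tolist(),
                        "log_density": self.densities_[c].log_density.tolist(),
                    }
                    for c in self.classes_
                },
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "BlockadeNBC":
        obj = json.loads(text)
        model = cls(n_bins=obj["n_bins"], edge_pad=obj["edge_pad"])
        model.classes_ = list(obj["classes"])
        model.log_prior_ = {c: float(v) for c, v in obj["log_prior"].items()}
        model.densities_ = {
            c: _ClassDensity(
                np.asarray(d["edges"], dtype=float),
                np.asarray(d["log_density"], dtype=float),
            )
            for c, d in obj["densities"].items()
        }
        return model


def classification_metrics(
    true_labels: Sequence[str], predicted_labels: Sequence[str]
) -> dict:
    """Confusion matrix with per-class precision/recall and overall accuracy."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label lists must have equal length")
    labels = sorted(set(true_labels) | set(predicted_labels))
    index = {c: i for i, c in enumerate(labels)}
    n = len(labels)
    confusion = np.zeros((n, n), dtype=np.int64)
    for t, p in zip(true_labels, predicted_labels):
        confusion[index[t], index[p]] += 1
    col = confusion.sum(axis=0)
    row = confusion.sum(axis=1)
    diag = np.diag(confusion).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(col > 0, diag / col, np.nan)
        recall = np.where(row > 0, diag / row, np.nan)
    accuracy = float(diag.sum() / confusion.sum())
    return {
        "labels": labels,
        "confusion": confusion,
        "precision": precision,
        "recall": recall,
        "accuracy": accuracy,
    }
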