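"""Fitted multiview model container and archive IO.

The model couples two topic-term distributions — phi_A over diagnoses and
phi_B over medications — through the single per-prescription topic
distribution theta they were trained under. The archive is a single ``.npz``
container holding the dense matrices plus a JSON metadata blob
(hyperparameters, vocabularies, training log, format version).
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .corpus import Vocabulary

__all__ = ["Hyperparams", "MVLDAModel", "ModelArchiveError", "save_model", "load_model"]

_ARCHIVE_VERSION = 1


@dataclass(frozen=True)
class Hyperparams:
    """Symmetric Dirichlet hyperparameters of the multiview model.

    ``alpha`` governs the per-prescription topic distribution theta;
    ``beta_A`` / ``beta_B`` govern the topic-diagnosis / topic-medication
    distributions. The default alpha = 0.1 is a sparse prior suited to
    prescriptions: with at most ~8 tokens per document, the classic long-text
    heuristic alpha = 50/K would contribute K*alpha = 50 pseudo-counts and
    drown the document itself, leaving topics unable to specialize.
    """

    K: int
    alpha: float | None = None
    beta_A: float = 0.01
    beta_B: float = 0.01

    def __post_init__(self):
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if self.alpha is None:
            object.__setattr__(self, "alpha", 0.1)
        if self.alpha <= 0 or self.beta_A <= 0 or self.beta_B <= 0:
            raise ValueError("alpha, beta_A, beta_B must be > 0")


class ModelArchiveError(ValueError):
    """Archive cannot be loaded: corrupted, wrong version, or inconsistent."""


@dataclass
class MVLDAModel:
    """Fitted model: row-stochastic phi_A (K x V_A), phi_B (K x V_B)."""

    phi_A: np.ndarray
    phi_B: np.ndarray
    hyper: Hyperparams
    vocab_A: Vocabulary
    vocab_B: Vocabulary
    training_log: dict = field(default_factory=dict)

    @property
    def K(self) -> int:
        return self.hyper.K

    def validate(self) -> None:
        K = self.hyper.K
        if self.phi_A.shape != (K, len(self.vocab_A)):
            raise ValueError(f"phi_A shape {self.phi_A.shape} != (K, V_A)")
        if self.phi_B.shape != (K, len(self.vocab_B)):
            raise ValueError(f"phi_B shape {self.phi_B.shape} != (K, V_B)")
        for name, phi in (("phi_A", self.phi_A), ("phi_B", self.phi_B)):
            if not np.allclose(phi.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"{name} rows must sum to 1")
            if not (phi > 0).all():
                raise ValueError(f"{name} entries must be > 0 (beta-smoothed)")


def save_model(model: MVLDAModel, path: str | Path) -> None:
    """Save a model archive; ``load_model`` recovers it exactly."""
    model.validate()
    meta = {
        "version": _ARCHIVE_VERSION,
        "hyper": {
            "K": model.hyper.K,
            "alpha": model.hyper.alpha,
            "beta_A": model.hyper.beta_A,
            "beta_B": model.hyper.beta_B,
        },
        "vocab_A": model.vocab_A.terms,
        "vocab_B": model.vocab_B.terms,
        "training_log": model.training_log,
    }
    np.savez(
        path,
        phi_A=model.phi_A,
        phi_B=model.phi_B,
        meta=np.frombuffer(json.dumps(meta).encode("utf-8"), dtype=np.uint8),
    )


def load_model(path: str | Path) -> MVLDAModel:
    try:
        with np.load(path) as data:
            phi_A = data["phi_A"]
            phi_B = data["phi_B"]
            meta = json.loads(bytes(data["meta"]).decode("utf-8"))
    except (OSError, KeyError, ValueError, zipfile.BadZipFile) as exc:
        raise ModelArchiveError(f"cannot load model archive {path}: {exc}") from exc
    if meta.get("version") != _ARCHIVE_VERSION:
        raise ModelArchiveError(
            f"archive version {meta.get('version')!r} unsupported "
            f"(expected {_ARCHIVE_VERSION})"
        )
    h = meta["hyper"]
    model = MVLDAModel(
        phi_A=phi_A,
        phi_B=phi_B,
        hyper=Hyperparams(K=h["K"], alpha=h["alpha"], beta_A=h["beta_A"], beta_B=h["beta_B"]),
        vocab_A=Vocabulary("A", meta["vocab_A"]),
        vocab_B=Vocabulary("B", meta["vocab_B"]),
        training_log=meta.get("training_log", {}),
    )
    try:
        model.validate()
    except ValueError as exc:
        raise ModelArchiveError(f"inconsistent model archive: {exc}") from exc
    return model
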