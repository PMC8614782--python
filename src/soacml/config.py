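"""Single structured configuration governing every pipeline stage.

All randomness flows from the named seeds here (split random states
default to 0/10/100; the synthetic seed lives inside the synthetic spec).
The correlation threshold is mandatory whenever selection runs: the cutoff
must be explicit for a run to be reproducible from its config alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .errors import SpecValidationError
from .suite import ALGORITHMS, IMPORTANCE_CAPABLE
from .synthetic import SyntheticSpec, spec_from_dict


@dataclass
class StudyConfig:
    """Validated study configuration (see ``default_config`` for defaults)."""

    # input: exactly one of compounds_path / synthetic
    compounds_path: Optional[str] = None
    synthetic: Optional[SyntheticSpec] = None
    k_ref: Optional[float] = None          # reference quenching rate constant

    backend: str = "stub"
    radius: int = 2
    n_bits: int = 2048

    threshold: float = 0.95                # correlation-pruning cutoff

    algorithms: tuple[str, ...] = ALGORITHMS
    random_states: tuple[int, ...] = (0, 10, 100)
    n_test: Optional[int] = None           # None -> 8-of-74 rule
    compute_loocv: bool = True
    hyperparameters: dict[str, dict] = field(default_factory=dict)

    top_k: int = 7

    def __post_init__(self):
        if self.threshold is None or not (0.0 < float(self.threshold) <= 1.0):
            raise SpecValidationError(
                "selection.threshold",
                f"correlation threshold must be set in (0, 1], got {self.threshold}")
        self.threshold = float(self.threshold)
        unknown = [a for a in self.algorithms if a not in ALGORITHMS]
        if unknown:
            raise SpecValidationError(
                "models.algorithms", f"unknown algorithms {unknown}; supported: {ALGORITHMS}")
        if not self.random_states:
            raise SpecValidationError("models.random_states", "must be non-empty")
        if self.radius < 0:
            raise SpecValidationError("featurization.radius", "must be >= 0")
        if self.n_bits < 1:
            raise SpecValidationError("featurization.n_bits", "must be >= 1")
        if self.top_k < 1:
            raise SpecValidationError("importance.top_k", "must be >= 1")
        self.algorithms = tuple(self.algorithms)
        self.random_states = tuple(int(r) for r in self.random_states)

    def to_dict(self) -> dict:
        d = {
            "input": {},
            "featurization": {"backend": self.backend, "radius": self.radius,
                              "n_bits": self.n_bits},
            "selection": {"threshold": self.threshold},
            "models": {"algorithms": list(self.algorithms),
                       "random_states": list(self.random_states),
                       "n_test": self.n_test,
                       "compute_loocv": self.compute_loocv,
                       "hyperparameters": self.hyperparameters},
            "importance": {"top_k": self.top_k},
        }
        if self.compounds_path is not None:
            d["input"]["compounds"] = str(self.compounds_path)
        if self.k_ref is not None:
            d["input"]["k_ref"] = self.k_ref
        if self.synthetic is not None:
            d["input"]["synthetic"] = {
                "n_samples": self.synthetic.n_samples,
                "n_descriptors": self.synthetic.n_descriptors,
                "n_fp_bits": self.synthetic.n_fp_bits,
                "blocks": [list(b) for b in self.synthetic.blocks],
                "fp_density": self.synthetic.fp_density,
                "planted": [list(p) for p in self.synthetic.planted],
                "noise_sd": self.synthetic.noise_sd,
                "seed": self.synthetic.seed,
            }
        return d


def config_from_dict(raw: dict) -> StudyConfig:
    raw = raw or {}
    inp = raw.get("input", {}) or {}
    feat = raw.get("featurization", {}) or {}
    sel = raw.get("selection", {}) or {}
    models = raw.get("models", {}) or {}
    imp = raw.get("importance", {}) or {}

    if "threshold" not in sel:
        raise SpecValidationError("selection.threshold",
                                  "missing — the correlation cutoff must be explicit")
    synthetic = inp.get("synthetic")
    if synthetic is not None:
        synthetic = spec_from_dict(synthetic)
    if synthetic is not None and inp.get("compounds") is not None:
        raise SpecValidationError("input", "give either compounds or synthetic, not both")
    if synthetic is None and inp.get("compounds") is None:
        raise SpecValidationError("input", "needs a compounds path or a synthetic spec")

    hp = models.get("hyperparameters", {}) or {}
    unknown_hp = [a for a in hp if a not in ALGORITHMS]
    if unknown_hp:
        raise SpecValidationError("models.hyperparameters",
                                  f"hyperparameters for unknown algorithms: {unknown_hp}")
    return StudyConfig(
        compounds_path=inp.get("compounds"),
        synthetic=synthetic,
        k_ref=inp.get("k_ref"),
        backend=feat.get("backend", "stub"),
        radius=int(feat.get("radius", 2)),
        n_bits=int(feat.get("n_bits", 2048)),
        threshold=sel["threshold"],
        algorithms=tuple(models.get("algorithms", ALGORITHMS)),
        random_states=tuple(models.get("random_states", (0, 10, 100))),
        n_test=models.get("n_test"),
        compute_loocv=bool(models.get("compute_loocv", True)),
        hyperparameters=hp,
        top_k=int(imp.get("top_k", 7)),
    )


def load_config(path: str | Path) -> StudyConfig:
    """Parse and validate a YAML config file (fails before any compute)."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise SpecValidationError("config", f"{path} is not a mapping")
    return config_from_dict(raw)


def default_config(synthetic: Optional[SyntheticSpec] = None,
                   compounds_path: Optional[str] = None,
                   **overrides) -> StudyConfig:
    """The documented defaults; importance-capable algorithms only."""
    return StudyConfig(synthetic=synthetic, compounds_path=compounds_path,
                       algorithms=overrides.pop("algorithms", IMPORTANCE_CAPABLE),
                       **overrides)
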