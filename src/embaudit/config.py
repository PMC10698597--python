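"""Configuration objects for the synthetic cohort generator and the audit.

Two dataclasses are defined here:

``SyntheticConfig``
    Generative parameters for a multi-site-style cohort with imbalanced
    demographic subgroups, subgroup-dependent disease prevalence, repeated
    scans per patient, and embeddings in which disease status, sex, and
    group membership each displace the feature distribution by configurable
    amounts.  The config doubles as the ground truth for recovery tests.

``AuditConfig``
    Knobs of the feature-space shift audit: how many leading PCA modes are
    tested, the significance level, the per-group subsample size, and the
    variance fraction retained before t-SNE.

Both round-trip through plain dictionaries and JSON/YAML files so that a
run's ground truth can be archived next to its outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "SyntheticConfig",
    "AuditConfig",
    "ConfigError",
    "load_config",
    "save_config",
    "config_hash",
]

_PROPORTION_TOL = 1e-9
_UNIT_NORM_TOL = 1e-9


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


def _as_tuple(x):
    if isinstance(x, np.ndarray):
        return tuple(x.tolist())
    if isinstance(x, (list, tuple)):
        return tuple(_as_tuple(v) if isinstance(v, (list, tuple, np.ndarray)) else v for v in x)
    return x


def _check_proportions(name: str, p: Sequence[float]) -> None:
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ConfigError(f"{name} must be non-empty")
    if np.any(p < 0):
        raise ConfigError(f"{name} must be nonnegative, got {p.tolist()}")
    if abs(p.sum() - 1.0) > _PROPORTION_TOL:
        raise ConfigError(f"{name} must sum to 1 within {_PROPORTION_TOL}, got sum {p.sum()!r}")


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground-truth parameters of the synthetic cohort and embedding model.

    Shift and effect sizes are expressed in units of ``noise_sd`` (the SD of
    the isotropic observation noise), so ``sex_shift=0.5`` displaces the two
    sex subgroups by half a noise SD along the sex direction.

    Direction vectors (``disease_directions``, ``sex_direction``,
    ``group_directions``) may be supplied explicitly as unit vectors; when
    left ``None`` a mutually orthonormal set is drawn deterministically from
    the seed.  Supplied vectors are Gram–Schmidt orthogonalized before use so
    the injected effects stay statistically separable.
    """

    n_patients: int = 2000
    scans_per_patient: tuple[int, ...] | int = (1, 2, 3)
    group_names: tuple[str, ...] = ("asian", "black", "white")
    group_proportions: tuple[float, ...] = (0.25, 0.15, 0.60)
    sex_proportions: tuple[float, float] = (0.55, 0.45)  # (male, female)
    age_mean_sd_per_group: tuple[tuple[float, float], ...] = ((63.0, 17.0),) * 3
    label_names: tuple[str, ...] = (
        "no_finding",
        "pleural_effusion",
        "cardiomegaly",
        "pneumothorax",
    )
    # prevalence[g][l] = P(label l positive | group g), one row per group
    prevalence: tuple[tuple[float, ...], ...] = (
        (0.30, 0.25, 0.15, 0.08),
        (0.28, 0.28, 0.18, 0.07),
        (0.32, 0.22, 0.14, 0.06),
    )
    embed_dim: int = 64
    # disease_effect_size[g][l], in units of noise_sd
    disease_effect_size: tuple[tuple[float, ...], ...] = (
        (1.5, 1.5, 1.5, 1.5),
        (1.5, 1.5, 1.5, 1.5),
        (1.5, 1.5, 1.5, 1.5),
    )
    sex_shift: float = 0.5
    group_shift: tuple[float, ...] = (0.0, 0.5, 0.25)
    disease_directions: tuple[tuple[float, ...], ...] | None = None
    sex_direction: tuple[float, ...] | None = None
    group_directions: tuple[tuple[float, ...], ...] | None = None
    patient_effect_sd: float = 0.5
    noise_sd: float = 1.0
    split_fractions: tuple[float, float, float] = (0.6, 0.1, 0.3)  # train/val/test
    age_range: tuple[float, float] = (18.0, 100.0)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "scans_per_patient", _as_tuple(self.scans_per_patient))
        for name in (
            "group_names",
            "group_proportions",
            "sex_proportions",
            "age_mean_sd_per_group",
            "label_names",
            "prevalence",
            "disease_effect_size",
            "group_shift",
            "disease_directions",
            "sex_direction",
            "group_directions",
            "split_fractions",
            "age_range",
        ):
            v = getattr(self, name)
            if v is not None:
                object.__setattr__(self, name, _as_tuple(v))
        self.validate()

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ConfigError("n_patients must be positive")
        if len(self.group_names) < 2:
            raise ConfigError("need at least 2 groups")
        if len(set(self.group_names)) != len(self.group_names):
            raise ConfigError("group names must be distinct")
        _check_proportions("group_proportions", self.group_proportions)
        _check_proportions("sex_proportions", self.sex_proportions)
        _check_proportions("split_fractions", self.split_fractions)
        if len(self.group_proportions) != self.n_groups:
            raise ConfigError("group_proportions length must match group_names")
        if len(self.age_mean_sd_per_group) != self.n_groups:
            raise ConfigError("age_mean_sd_per_group length must match group_names")
        if len(self.sex_proportions) != 2:
            raise ConfigError("sex_proportions must have exactly two entries (male, female)")
        if len(self.label_names) == 0:
            raise ConfigError("need at least one label")
        prev = np.asarray(self.prevalence, dtype=float)
        if prev.shape != (self.n_groups, self.n_labels):
            raise ConfigError(
                f"prevalence must have shape (n_groups, n_labels) = "
                f"({self.n_groups}, {self.n_labels}), got {prev.shape}"
            )
        if np.any((prev < 0) | (prev > 1)):
            raise ConfigError("prevalences must lie in [0, 1]")
        eff = np.asarray(self.disease_effect_size, dtype=float)
        if eff.shape != (self.n_groups, self.n_labels):
            raise ConfigError("disease_effect_size must have shape (n_groups, n_labels)")
        if np.any(eff < 0):
            raise ConfigError("disease effect sizes must be nonnegative")
        if len(self.group_shift) != self.n_groups:
            raise ConfigError("group_shift length must match group_names")
        if any(s < 0 for s in self.group_shift):
            raise ConfigError("group shifts must be nonnegative")
        if self.sex_shift < 0:
            raise ConfigError("sex_shift must be nonnegative")
        if self.patient_effect_sd < 0:
            raise ConfigError("patient_effect_sd must be nonnegative")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        spp = self.scans_per_patient
        spp = (spp,) if isinstance(spp, int) else spp
        if len(spp) == 0 or any((not isinstance(k, (int, np.integer))) or k < 1 for k in spp):
            raise ConfigError("scans_per_patient must be a positive int or tuple of them")
        if self.embed_dim < self.n_direction_vectors:
            raise ConfigError(
                f"embed_dim ({self.embed_dim}) must be at least the number of "
                f"direction vectors ({self.n_direction_vectors})"
            )
        for name, vecs, expect in (
            ("disease_directions", self.disease_directions, self.n_labels),
            ("group_directions", self.group_directions, self.n_groups),
        ):
            if vecs is not None:
                arr = np.asarray(vecs, dtype=float)
                if arr.shape != (expect, self.embed_dim):
                    raise ConfigError(f"{name} must have shape ({expect}, {self.embed_dim})")
                norms = np.linalg.norm(arr, axis=1)
                if np.any(np.abs(norms - 1) > _UNIT_NORM_TOL):
                    raise ConfigError(f"{name} rows must have unit norm within {_UNIT_NORM_TOL}")
        if self.sex_direction is not None:
            v = np.asarray(self.sex_direction, dtype=float)
            if v.shape != (self.embed_dim,):
                raise ConfigError(f"sex_direction must have length {self.embed_dim}")
            if abs(np.linalg.norm(v) - 1) > _UNIT_NORM_TOL:
                raise ConfigError("sex_direction must have unit norm")

    # -- derived quantities --------------------------------------------
    @property
    def n_groups(self) -> int:
        return len(self.group_names)

    @property
    def n_labels(self) -> int:
        return len(self.label_names)

    @property
    def n_direction_vectors(self) -> int:
        return self.n_labels + 1 + self.n_groups

    @property
    def scans_per_patient_choices(self) -> tuple[int, ...]:
        spp = self.scans_per_patient
        return (spp,) if isinstance(spp, int) else tuple(spp)

    def replace(self, **kwargs) -> "SyntheticConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown SyntheticConfig keys: {sorted(unknown)}")
        return cls(**d)


@dataclass(frozen=True)
class AuditConfig:
    """Parameters of the feature-space shift audit."""

    n_modes_tested: int = 4
    alpha: float = 0.05
    per_group_subsample: int = 1000
    variance_retention_for_tsne: float = 0.99
    tsne_perplexity: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ConfigError("alpha must lie in (0, 1)")
        if not (0 < self.variance_retention_for_tsne <= 1):
            raise ConfigError("variance_retention_for_tsne must lie in (0, 1]")
        if self.n_modes_tested < 1:
            raise ConfigError("n_modes_tested must be positive")
        if self.per_group_subsample < 0:
            raise ConfigError("per_group_subsample must be nonnegative")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "AuditConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown AuditConfig keys: {sorted(unknown)}")
        return cls(**d)

    def replace(self, **kwargs) -> "AuditConfig":
        return dataclasses.replace(self, **kwargs)


def save_config(config, path: str | Path) -> None:
    """Write a config dataclass to JSON or YAML (chosen by extension)."""
    path = Path(path)
    d = config.to_dict()
    if path.suffix in {".yaml", ".yml"}:
        path.write_text(yaml.safe_dump(d, sort_keys=True))
    else:
        path.write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")


def load_config(path: str | Path, cls=SyntheticConfig):
    """Read a config dataclass from a JSON or YAML file."""
    path = Path(path)
    text = path.read_text()
    d = yaml.safe_load(text) if path.suffix in {".yaml", ".yml"} else json.loads(text)
    return cls.from_dict(d)


def config_hash(config) -> str:
    """Short stable hash of a config, for output manifests."""
    payload = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
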