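"""Synthetic cohorts of labelled multi-frequency impedance matrices.

Each simulated subject is a lumped circuit: every electrode pair measures
the two electrode-skin contact impedances in series with a weighted mix
of a liver path and a background (torso) path, each a Cole-type
dispersion.  Fatty-liver subjects carry an elevated zero-frequency liver
resistance, so their matrices sit above healthy ones at the low end of
the sweep — the contrast the classifier must pick up.

Cohort generation draws per-subject circuit parameters from
label-conditional log-normal distributions around the configured class
medians, applies per-cell multiplicative log-normal measurement noise,
and is a pure function of its seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .circuits import (
    ElectrodeSkinModel,
    FrequencyGrid,
    TissueDispersion,
    electrode_skin_impedance,
    frequency_grid,
    tissue_path_impedance,
)
from .geometry import SensorGeometry, default_geometry

__all__ = [
    "SubjectParams",
    "ImpedanceMatrix",
    "CohortDataset",
    "GeneratorConfig",
    "simulate_matrix",
    "generate_cohort",
    "save_cohort",
    "load_cohort",
]

HEALTHY = "healthy"
NAFLD = "nafld"
LABELS = (HEALTHY, NAFLD)


@dataclass(frozen=True)
class SubjectParams:
    """Full circuit description of one simulated subject."""

    label: str
    liver: TissueDispersion
    background: TissueDispersion
    contacts: tuple[ElectrodeSkinModel, ...]
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass(frozen=True)
class ImpedanceMatrix:
    """|Z| grid for one subject: rows = electrode pairs, columns = frequencies."""

    magnitudes: np.ndarray
    label: str
    subject_id: str

    def __post_init__(self) -> None:
        m = np.asarray(self.magnitudes, dtype=float)
        if m.ndim != 2:
            raise ValueError("magnitudes must be 2-D (pairs x frequencies)")
        if not np.all(np.isfinite(m)) or np.any(m <= 0):
            raise ValueError("magnitudes must be positive and finite")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        object.__setattr__(self, "magnitudes", m)

    @property
    def shape(self) -> tuple[int, int]:
        return self.magnitudes.shape


@dataclass
class CohortDataset:
    """Labelled collection of impedance matrices plus the generating seed."""

    matrices: list[ImpedanceMatrix]
    seed: int = 0

    def __len__(self) -> int:
        return len(self.matrices)

    @property
    def labels(self) -> np.ndarray:
        return np.array([m.label for m in self.matrices])

    @property
    def y(self) -> np.ndarray:
        """Binary targets: 1 for fatty liver, 0 for healthy."""
        return (self.labels == NAFLD).astype(int)

    @property
    def subject_ids(self) -> np.ndarray:
        return np.array([m.subject_id for m in self.matrices])

    def stack(self) -> np.ndarray:
        """Matrices stacked to (subjects, pairs, frequencies)."""
        return np.stack([m.magnitudes for m in self.matrices])


@dataclass(frozen=True)
class GeneratorConfig:
    """Class medians, between-subject spread and noise for cohort generation.

    Class medians are the shipped synthetic-world defaults: a healthy
    liver path around 500 ohm at DC, a fatty one around 1000 ohm (lipid
    accumulation impedes low-frequency current), a shared background
    path, and low-impedance electrode contacts.  Coefficients of
    variation (`cv_*`) are the log-normal scales of between-subject
    variability; `noise_sigma` is the per-cell multiplicative
    measurement-noise scale.
    """

    healthy_liver: TissueDispersion = TissueDispersion(R0=500.0, Rinf=200.0, fc=3e4, alpha=0.8)
    nafld_liver: TissueDispersion = TissueDispersion(R0=1000.0, Rinf=300.0, fc=1.5e4, alpha=0.8)
    background: TissueDispersion = TissueDispersion(R0=400.0, Rinf=150.0, fc=5e4, alpha=0.85)
    contact: ElectrodeSkinModel = ElectrodeSkinModel(R_d=100.0, C_dl=1e-6, R_e=1e4)
    cv_liver: float = 0.06
    cv_fc: float = 0.05
    cv_background: float = 0.04
    cv_contact: float = 0.08
    noise_sigma: float = 0.03
    formula1_literal: bool = False

    def to_dict(self) -> dict:
        d = {}
        for key in ("healthy_liver", "nafld_liver", "background"):
            t: TissueDispersion = getattr(self, key)
            d[key] = {"R0": t.R0, "Rinf": t.Rinf, "fc": t.fc, "alpha": t.alpha}
        c = self.contact
        d["contact"] = {"R_d": c.R_d, "C_dl": c.C_dl, "R_e": c.R_e}
        for key in ("cv_liver", "cv_fc", "cv_background", "cv_contact", "noise_sigma", "formula1_literal"):
            d[key] = getattr(self, key)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        kwargs = dict(d)
        for key in ("healthy_liver", "nafld_liver", "background"):
            if key in kwargs:
                kwargs[key] = TissueDispersion(**kwargs[key])
        if "contact" in kwargs:
            kwargs["contact"] = ElectrodeSkinModel(**kwargs["contact"])
        return cls(**kwargs)


def simulate_matrix(
    subject: SubjectParams,
    geometry: SensorGeometry | None = None,
    grid: FrequencyGrid | None = None,
    rng_seed: int = 0,
    *,
    formula1_literal: bool = False,
    subject_id: str = "S00",
) -> ImpedanceMatrix:
    """Forward-simulate one subject's (pairs x frequencies) |Z| matrix.

    For pair ``p = (e1, e2)`` at frequency ``f`` the noise-free cell is
    ``|Z_contact(e1,f) + Z_contact(e2,f) + w_p Z_liver(f) + (1-w_p) Z_background(f)|``
    with ``w_p`` the pair's liver path fraction; each cell is then scaled
    by an i.i.d. log-normal factor of median 1 and log-scale
    ``noise_sigma``.  Deterministic given ``rng_seed``; with
    ``noise_sigma = 0`` the seed is irrelevant.
    """
    geometry = geometry if geometry is not None else default_geometry()
    grid = grid if grid is not None else frequency_grid()
    if len(subject.contacts) != geometry.n_electrodes:
        raise ValueError(
            f"subject has {len(subject.contacts)} contacts but geometry expects {geometry.n_electrodes}"
        )
    f = grid.frequencies
    z_contact = np.stack(
        [electrode_skin_impedance(c, f, literal=formula1_literal) for c in subject.contacts]
    )  # (n_electrodes, n_freq)
    z_liver = tissue_path_impedance(subject.liver, f)
    z_bg = tissue_path_impedance(subject.background, f)
    rows = []
    for (e1, e2), w in zip(geometry.pairs, geometry.liver_weight):
        z = z_contact[e1] + z_contact[e2] + w * z_liver + (1.0 - w) * z_bg
        rows.append(np.abs(z))
    mags = np.stack(rows)
    if subject.noise_sigma > 0:
        rng = np.random.default_rng(rng_seed)
        mags = mags * np.exp(subject.noise_sigma * rng.standard_normal(mags.shape))
    return ImpedanceMatrix(magnitudes=mags, label=subject.label, subject_id=subject_id)


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    return float(np.exp(cv * rng.standard_normal()))


def _draw_subject(rng: np.random.Generator, label: str, cfg: GeneratorConfig, n_electrodes: int) -> SubjectParams:
    liver_med = cfg.nafld_liver if label == NAFLD else cfg.healthy_liver
    liver = TissueDispersion(
        R0=liver_med.R0 * _lognormal_factor(rng, cfg.cv_liver),
        Rinf=liver_med.Rinf * _lognormal_factor(rng, cfg.cv_liver),
        fc=liver_med.fc * _lognormal_factor(rng, cfg.cv_fc),
        alpha=liver_med.alpha,
    )
    bg = cfg.background
    background = TissueDispersion(
        R0=bg.R0 * _lognormal_factor(rng, cfg.cv_background),
        Rinf=bg.Rinf * _lognormal_factor(rng, cfg.cv_background),
        fc=bg.fc * _lognormal_factor(rng, cfg.cv_fc),
        alpha=bg.alpha,
    )
    contacts = tuple(
        ElectrodeSkinModel(
            R_d=cfg.contact.R_d * _lognormal_factor(rng, cfg.cv_contact),
            C_dl=cfg.contact.C_dl * _lognormal_factor(rng, cfg.cv_contact),
            R_e=cfg.contact.R_e * _lognormal_factor(rng, cfg.cv_contact),
        )
        for _ in range(n_electrodes)
    )
    return SubjectParams(
        label=label, liver=liver, background=background, contacts=contacts, noise_sigma=cfg.noise_sigma
    )


def generate_cohort(
    n_healthy: int = 20,
    n_nafld: int = 20,
    config: GeneratorConfig | None = None,
    seed: int = 0,
    *,
    geometry: SensorGeometry | None = None,
    grid: FrequencyGrid | None = None,
) -> CohortDataset:
    """Generate a labelled cohort (default: 20 healthy + 20 fatty-liver).

    Per-subject dispersion and contact parameters are drawn from
    label-conditional log-normal distributions around the configured
    medians; the whole cohort is reproducible from ``seed``.
    """
    if n_healthy < 0 or n_nafld < 0:
        raise ValueError("subject counts must be >= 0")
    cfg = config if config is not None else GeneratorConfig()
    geometry = geometry if geometry is not None else default_geometry()
    grid = grid if grid is not None else frequency_grid()
    rng = np.random.default_rng(seed)
    matrices: list[ImpedanceMatrix] = []
    spec = [(HEALTHY, "H", n_healthy), (NAFLD, "N", n_nafld)]
    for label, prefix, count in spec:
        for i in range(count):
            subject = _draw_subject(rng, label, cfg, geometry.n_electrodes)
            noise_seed = int(rng.integers(0, 2**31 - 1))
            matrices.append(
                simulate_matrix(
                    subject,
                    geometry,
                    grid,
                    rng_seed=noise_seed,
                    formula1_literal=cfg.formula1_literal,
                    subject_id=f"{prefix}{i + 1:02d}",
                )
            )
    return CohortDataset(matrices=matrices, seed=seed)


def save_cohort(cohort: CohortDataset, path: str | Path) -> None:
    """Write a cohort as a stacked array + CSV metadata sidecar.

    ``path`` is a directory holding ``matrices.npy`` (subjects x pairs x
    frequencies, float64), ``metadata.csv`` (subject_id, label) and
    ``cohort.json`` (seed, shape).  The round trip is lossless.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    stacked = cohort.stack() if len(cohort) else np.zeros((0, 0, 0))
    np.save(path / "matrices.npy", stacked)
    pd.DataFrame({"subject_id": cohort.subject_ids, "label": cohort.labels}).to_csv(
        path / "metadata.csv", index=False
    )
    (path / "cohort.json").write_text(
        json.dumps({"seed": cohort.seed, "n_subjects": len(cohort), "shape": list(stacked.shape)})
    )


def load_cohort(path: str | Path) -> CohortDataset:
    """Inverse of :func:`save_cohort`, with consistency checks."""
    path = Path(path)
    for name in ("matrices.npy", "metadata.csv", "cohort.json"):
        if not (path / name).exists():
            raise FileNotFoundError(f"cohort file missing: {path / name}")
    meta = json.loads((path / "cohort.json").read_text())
    stacked = np.load(path / "matrices.npy")
    table = pd.read_csv(path / "metadata.csv") if meta["n_subjects"] else pd.DataFrame(columns=["subject_id", "label"])
    if len(table) != meta["n_subjects"] or stacked.shape[0] != meta["n_subjects"]:
        raise ValueError(
            f"corrupt cohort at {path}: metadata rows ({len(table)}) or stack "
            f"({stacked.shape[0]}) disagree with recorded n_subjects ({meta['n_subjects']})"
        )
    matrices = [
        ImpedanceMatrix(magnitudes=stacked[i], label=row.label, subject_id=row.subject_id)
        for i, row in enumerate(table.itertuples())
    ]
    return CohortDataset(matrices=matrices, seed=int(meta["seed"]))
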