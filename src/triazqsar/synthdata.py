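"""Synthetic inputs with the statistical structure the pipeline assumes.

Real descriptor tables and aligned, charged geometries come from external
quantum-chemistry tooling; these generators emulate their structure so every
pipeline stage is testable offline with known ground truth:

* descriptor matrices with a planted sparse linear activity model plus
  Gaussian noise (optionally collinear descriptors);
* sets of "aligned" molecules: copies of a scaffold with per-atom coordinate
  jitter and zero-sum charge perturbations on a shared frame;
* activities generated from a planted weight map over post-preprocessing
  field columns.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .mif_engine import (
    AlignedMoleculeSet,
    Grid,
    GridSpec,
    MifMatrix,
    Molecule,
    PreprocessConfig,
    ProbeParams,
    compute_fields,
    make_grid,
    preprocess_fields,
)
from .qsar2d import DescriptorMatrix

__all__ = [
    "Synthetic2DConfig",
    "SyntheticMifConfig",
    "gen_descriptor_data",
    "gen_molecule_set",
    "gen_field_activity",
    "gen_grouped_benchmark",
    "triazine_like_scaffold",
    "triazine_like_benchmark",
]


@dataclass(frozen=True)
class Synthetic2DConfig:
    """Descriptor-matrix generator settings.

    ``true_coefficients`` maps descriptor index -> coefficient; descriptors
    are standard normal (independent unless a covariance is supplied) and
    ``y = intercept + X a + N(0, noise_sd)``.
    """

    n_compounds: int = 20
    n_descriptors: int = 10
    true_intercept: float = 6.302
    true_coefficients: dict[int, float] = field(
        default_factory=lambda: {0: 6.182, 1: 0.946, 2: 0.062}
    )
    noise_sd: float = 0.1
    seed: int = 0
    covariance: tuple[tuple[float, ...], ...] | None = None

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        bad = [j for j in self.true_coefficients if not 0 <= j < self.n_descriptors]
        if bad:
            raise ValueError(f"coefficient indices out of range: {bad}")


def gen_descriptor_data(
    config: Synthetic2DConfig,
) -> tuple[DescriptorMatrix, np.ndarray, dict]:
    """Returns (DescriptorMatrix, pIC50 vector, truth record)."""
    rng = np.random.default_rng(config.seed)
    n, p = config.n_compounds, config.n_descriptors
    if config.covariance is not None:
        cov = np.asarray(config.covariance, dtype=float)
        X = rng.multivariate_normal(np.zeros(p), cov, size=n)
    else:
        X = rng.standard_normal((n, p))
    a = np.zeros(p)
    for j, coef in config.true_coefficients.items():
        a[j] = coef
    y = config.true_intercept + X @ a + rng.normal(0.0, config.noise_sd, size=n)
    names = [f"D{j:03d}" for j in range(p)]
    truth = {
        "intercept": config.true_intercept,
        "coefficients": {names[j]: c for j, c in config.true_coefficients.items()},
        "noise_sd": config.noise_sd,
        "seed": config.seed,
    }
    return DescriptorMatrix(list(range(1, n + 1)), names, X), y, truth


def triazine_like_scaffold() -> tuple[list[str], np.ndarray, np.ndarray]:
    """A small heteroaromatic scaffold with substituent arms, loosely shaped
    like a 2-chloro-4,6-diamino-s-triazine: a six-membered C3N3 ring, a
    chlorine, and two amino arms.  Charges are chemically plausible signs
    (ring N negative, ring C positive, Cl slightly negative) and sum to zero.
    """
    ring_r = 1.35
    elements: list[str] = []
    coords: list[list[float]] = []
    charges: list[float] = []
    for i in range(6):
        ang = np.pi / 3 * i
        elements.append("N" if i % 2 == 0 else "C")
        coords.append([ring_r * np.cos(ang), ring_r * np.sin(ang), 0.0])
        charges.append(-0.35 if i % 2 == 0 else 0.30)
    # chlorine on C1, two N-substituent arms on C3 and C5
    arm_specs = [(1, "Cl", 1.75, -0.10), (3, "N", 1.40, -0.25), (5, "N", 1.40, -0.25)]
    for ring_idx, el, bond, q in arm_specs:
        ang = np.pi / 3 * ring_idx
        direction = np.array([np.cos(ang), np.sin(ang), 0.0])
        base = np.array(coords[ring_idx]) + bond * direction
        elements.append(el)
        coords.append(base.tolist())
        charges.append(q)
        if el == "N":  # short alkyl arm off each amino nitrogen
            for step, dz in ((1.5, 0.5), (2.9, 0.9)):
                elements.append("C")
                coords.append((base + step * direction + np.array([0, 0, dz])).tolist())
                charges.append(0.05)
    q = np.array(charges)
    q -= q.mean()  # exactly neutral
    return elements, np.array(coords), q


def gen_grouped_benchmark(
    seed: int = 0,
    n_samples: int = 60,
    n_signal_groups: int = 5,
    n_noise_groups: int = 15,
    cols_per_signal: int = 3,
    cols_per_noise: int = 5,
    noise_scale: float = 2.0,
    y_noise_sd: float = 0.1,
) -> tuple[np.ndarray, np.ndarray, list[list[int]], int]:
    """Grouped-variable screening benchmark with known ground truth.

    Signal groups are noisy copies of mutually orthonormal latent factors
    (each factor carries unique information about y, mimicking distinct
    spatial regions that each report a different substituent effect); noise
    groups are pure Gaussian columns.  ``y`` is the sum of the factors plus
    noise.  Returns (X, y, groups, n_signal_groups) with the signal groups
    listed first.
    """
    rng = np.random.default_rng(seed)
    F, _ = np.linalg.qr(rng.standard_normal((n_samples, n_signal_groups)))
    F *= np.sqrt(n_samples)
    y = F.sum(axis=1) + y_noise_sd * rng.standard_normal(n_samples)
    groups: list[list[int]] = []
    mats = []
    col = 0
    for g in range(n_signal_groups + n_noise_groups):
        if g < n_signal_groups:
            block = F[:, g][:, None] + 0.2 * rng.standard_normal(
                (n_samples, cols_per_signal)
            )
            k = cols_per_signal
        else:
            block = noise_scale * rng.standard_normal((n_samples, cols_per_noise))
            k = cols_per_noise
        mats.append(block)
        groups.append(list(range(col, col + k)))
        col += k
    return np.concatenate(mats, axis=1), y, groups, n_signal_groups


@dataclass(frozen=True)
class SyntheticMifConfig:
    """Aligned-molecule-set generator settings.

    Each molecule is the scaffold with Gaussian coordinate jitter of SD
    ``substituent_perturbation_sd`` (angstrom, all atoms) and zero-sum charge
    jitter of SD ``charge_perturbation_sd``; the shared frame needs no
    re-alignment.
    """

    n_molecules: int = 20
    substituent_perturbation_sd: float = 0.3
    charge_perturbation_sd: float = 0.05
    noise_sd: float = 0.1
    n_signal_columns: int = 10
    weight_scale: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_molecules < 1:
            raise ValueError("need at least one molecule")
        if min(self.substituent_perturbation_sd, self.charge_perturbation_sd,
               self.noise_sd) < 0:
            raise ValueError("perturbation/noise SDs must be >= 0")


def gen_molecule_set(
    config: SyntheticMifConfig,
    scaffold: tuple[list[str], np.ndarray, np.ndarray] | None = None,
) -> AlignedMoleculeSet:
    """Jittered copies of the scaffold on one shared frame."""
    elements, coords, charges = scaffold if scaffold is not None else triazine_like_scaffold()
    rng = np.random.default_rng(config.seed)
    mols = []
    for i in range(config.n_molecules):
        jitter = rng.normal(0.0, config.substituent_perturbation_sd, size=coords.shape)
        dq = rng.normal(0.0, config.charge_perturbation_sd, size=len(charges))
        dq -= dq.mean()  # molecules stay neutral-comparable
        mols.append(Molecule(i + 1, list(elements), coords + jitter, charges + dq))
    return AlignedMoleculeSet(mols)


def gen_field_activity(
    mif: MifMatrix,
    config: SyntheticMifConfig,
    true_weight_map: dict[int, float] | None = None,
    n_latent: int = 3,
) -> tuple[np.ndarray, dict]:
    """Activities from a planted weight vector over kept field columns.

    Two planting modes:

    * explicit ``true_weight_map`` (kept-column index -> weight): used
      verbatim, ``y = offset + X w + noise``; raises if a requested column
      did not survive preprocessing.  Arbitrary sparse maps over thousands
      of collinear grid columns are generally *not* identifiable from a
      handful of molecules — use this mode for localized-signal tests, not
      coefficient recovery.
    * default: the weight vector is drawn inside the span of the kept
      matrix's ``n_latent`` leading principal directions and rescaled so
      the noiseless activities span about 6.3-9.6 pIC50 (the dynamic range
      of a strongly varying congeneric immunoassay series).  This truth is
      identifiable: a PLS model with ``n_latent`` components recovers it
      exactly at zero noise.
    """
    rng = np.random.default_rng(config.seed + 1)
    Xk = mif.X
    n, p = Xk.shape
    if p == 0:
        raise ValueError(
            "no field columns survived preprocessing; increase "
            "substituent_perturbation_sd"
        )
    Xc = Xk - Xk.mean(axis=0)
    if true_weight_map is not None:
        bad = [c for c in true_weight_map if not 0 <= c < p]
        if bad:
            raise ValueError(f"planted columns not in the kept matrix: {bad}")
        w = np.zeros(p)
        for c, weight in true_weight_map.items():
            w[c] = weight
        offset = 8.0
    else:
        k = min(n_latent, n - 1, p)
        _, s, vt = np.linalg.svd(Xc, full_matrices=False)
        d = rng.standard_normal(k) * np.linspace(1.0, 0.5, k)
        w = vt[:k].T @ (d / np.maximum(s[:k], 1e-12) * s[0])
        span = (Xc @ w).max() - (Xc @ w).min()
        w *= 3.3 / span  # pIC50 range ~ 6.3-9.6
        raw = Xk @ w
        offset = 7.95 - float(raw.min() + raw.max()) / 2.0
    signal = Xk @ w
    if np.std(signal) == 0:
        raise ValueError("planted weights carry no variance; increase perturbation")
    y = offset + signal + rng.normal(0.0, config.noise_sd, size=n)
    truth = {
        "weight_map": dict(true_weight_map) if true_weight_map is not None else None,
        "weights_dense": w,
        "offset": offset,
        "noise_sd": config.noise_sd,
        "seed": config.seed,
        "n_latent": None if true_weight_map is not None else int(min(n_latent, n - 1, p)),
    }
    return y, truth


def triazine_like_benchmark(
    seed: int = 0,
    noise_sd: float = 0.1,
    n_molecules: int = 20,
    spacing: float = 2.0,
    preprocess: PreprocessConfig | None = None,
) -> tuple[AlignedMoleculeSet, Grid, MifMatrix, np.ndarray, dict]:
    """The standard synthetic 3D benchmark: 20 scaffold variants on the
    study-sized lattice (26 x 18 x 22 angstrom, 2 angstrom spacing), both
    fields computed and preprocessed, activities spanning a few pIC50 units
    from a planted weight map."""
    config = SyntheticMifConfig(n_molecules=n_molecules, noise_sd=noise_sd, seed=seed)
    molecules = gen_molecule_set(config)
    grid = make_grid(GridSpec(extents=(26.0, 18.0, 22.0), spacing=spacing), molecules)
    blocks = compute_fields(molecules, grid, ProbeParams())
    mif = preprocess_fields(blocks, preprocess or PreprocessConfig(), grid=grid)
    y, truth = gen_field_activity(mif, config)
    return molecules, grid, mif, y, truth
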