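"""Conformer-ensemble 3D polar surface area.

For each conformer the exposed van-der-Waals surface (probe radius 0) of
the polar atoms — nitrogen, oxygen and hydrogens bonded to either — is
integrated by deterministic spiral-point sampling with occlusion testing
against every other atom. Ensembles are summarised by median, quartiles
and Tukey adjacent limits (the extreme data values inside the inner
fences Q1 - 1.5*IQR and Q3 + 1.5*IQR), the whisker bounds of a violin
plot.

Flexible molecules in solution populate conformers of widely differing
polarity, so the five representative statistics can each be regressed
against log S to ask whether any region of the 3D-PSA distribution models
solubility better than the 2D TPSA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .errors import DomainError, InsufficientDataError, ParameterizationError

# Bondi van-der-Waals radii, Å
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "Cl": 1.75, "Br": 1.85, "I": 1.98,
}

DEFAULT_N_POINTS = 960
# an H this close to N/O (Å) is taken as bonded to it
POLAR_H_BOND_CUTOFF = 1.30


@dataclass
class Conformer:
    elements: tuple[str, ...]
    coords: np.ndarray  # (n_atoms, 3) Å

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.elements), 3):
            raise DomainError(
                f"coordinate array {self.coords.shape} does not match {len(self.elements)} atoms")


@dataclass
class ConformerEnsemble:
    compound_id: str
    conformers: list[Conformer] = field(default_factory=list)
    source: str = "other"  # CS | SMD | other


@dataclass
class PSADistribution:
    """Five-number ensemble summary of per-conformer 3D-PSA values (Å²)."""

    per_conformer_psa: list[float]
    median: float
    q1: float
    q3: float
    lower_adjacent: float
    upper_adjacent: float


def sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral point set on the unit sphere."""
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * math.pi * (3.0 - math.sqrt(5.0))
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def polar_atom_mask(conformer: Conformer, *, include_sulfur: bool = False) -> np.ndarray:
    """True for atoms contributing polar surface: N, O (optionally S) and
    hydrogens whose nearest N/O lies within bonding distance."""
    elements = conformer.elements
    polar_heavy = {"N", "O"} | ({"S"} if include_sulfur else set())
    mask = np.array([e in polar_heavy for e in elements])
    heavy_idx = [i for i, e in enumerate(elements) if e in {"N", "O"}]
    if heavy_idx:
        for i, e in enumerate(elements):
            if e != "H":
                continue
            d = np.linalg.norm(conformer.coords[heavy_idx] - conformer.coords[i], axis=1)
            if d.min() <= POLAR_H_BOND_CUTOFF:
                mask[i] = True
    return mask


def compute_3d_psa(
    conformer: Conformer,
    *,
    n_points: int = DEFAULT_N_POINTS,
    include_sulfur: bool = False,
    point_set: Optional[np.ndarray] = None,
) -> float:
    """Exposed polar van-der-Waals surface area (probe radius 0), Å².

    Each polar atom's sphere is sampled with ``n_points`` spiral points; a
    point survives if it lies outside every other atom's sphere. The result
    is deterministic for a fixed point set and bounded above by the sum of
    the isolated polar-atom sphere areas (equality iff no occlusion).
    """
    coords = conformer.coords
    if not np.all(np.isfinite(coords)):
        raise DomainError("non-finite coordinates")
    radii = np.empty(len(conformer.elements))
    for i, e in enumerate(conformer.elements):
        if e not in VDW_RADII:
            raise ParameterizationError(f"no van-der-Waals radius for element {e!r}")
        radii[i] = VDW_RADII[e]
    mask = polar_atom_mask(conformer, include_sulfur=include_sulfur)
    unit = sphere_points(n_points) if point_set is None else np.asarray(point_set, dtype=float)
    n_pts = len(unit)
    area = 0.0
    for i in np.flatnonzero(mask):
        pts = coords[i] + radii[i] * unit
        exposed = np.ones(n_pts, dtype=bool)
        for j in range(len(radii)):
            if j == i:
                continue
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            exposed &= d2 >= radii[j] ** 2
        area += 4.0 * math.pi * radii[i] ** 2 * exposed.sum() / n_pts
    return float(area)


def ensemble_psa(
    ensemble: ConformerEnsemble,
    *,
    n_points: int = DEFAULT_N_POINTS,
    include_sulfur: bool = False,
) -> list[float]:
    """Per-conformer 3D-PSA over a whole ensemble (shared point set)."""
    unit = sphere_points(n_points)
    return [
        compute_3d_psa(c, include_sulfur=include_sulfur, point_set=unit)
        for c in ensemble.conformers
    ]


def summarize_ensemble(psa_values: Sequence[float]) -> PSADistribution:
    """Quartiles (linear interpolation) and Tukey adjacent limits.

    The lower adjacent limit is the smallest value >= Q1 - 1.5*IQR; the
    upper adjacent limit is the largest value <= Q3 + 1.5*IQR. If no datum
    lies inside a fence (extreme outlier-dominated lists) the limit
    degrades to the quartile itself.
    """
    values = np.asarray(psa_values, dtype=float)
    if values.size == 0:
        raise DomainError("empty PSA value list")
    q1, median, q3 = (float(v) for v in np.percentile(values, [25, 50, 75]))
    iqr = q3 - q1
    lower_fence = q1 - 1.5 * iqr
    upper_fence = q3 + 1.5 * iqr
    inside_low = values[values >= lower_fence]
    inside_high = values[values <= upper_fence]
    lower_adj = float(inside_low.min()) if inside_low.size else q1
    upper_adj = float(inside_high.max()) if inside_high.size else q3
    lower_adj = min(lower_adj, q1)
    upper_adj = max(upper_adj, q3)
    return PSADistribution(
        per_conformer_psa=[float(v) for v in values],
        median=median, q1=q1, q3=q3,
        lower_adjacent=lower_adj, upper_adjacent=upper_adj,
    )


REPRESENTATIVE_STATISTICS = ("lower_adjacent", "q1", "median", "q3", "upper_adjacent")


def representative_psa_regressions(
    distributions: dict[str, PSADistribution],
    log_s: dict[str, float],
):
    """OLS of log S on each representative 3D-PSA statistic.

    Returns a DataFrame with one row per statistic (slope, intercept, r2,
    n) over the compounds that have both an ensemble summary and a
    quantitative log S.
    """
    import pandas as pd

    from .models import fit_linear

    ids = sorted(set(distributions) & set(log_s))
    if len(ids) < 3:
        raise InsufficientDataError(
            f"need >=3 compounds with both PSA and log S, got {len(ids)}")
    y = [log_s[i] for i in ids]
    rows = []
    for stat in REPRESENTATIVE_STATISTICS:
        x = [getattr(distributions[i], stat) for i in ids]
        lm = fit_linear(x, y, x_name=stat, y_name="log_s")
        rows.append({"statistic": stat, "slope": lm.slope, "intercept": lm.intercept,
                     "r2": lm.r2, "n": lm.n})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# ensemble file ingestion (multi-conformer SDF / multi-model PDB)
# --------------------------------------------------------------------------

def read_ensemble_sdf(path: Union[str, Path], compound_id: Optional[str] = None) -> ConformerEnsemble:
    """Read every record of an SDF file as one conformer of one ensemble."""
    from rdkit import Chem

    path = Path(path)
    ens = ConformerEnsemble(compound_id=compound_id or path.stem)
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    for mol in supplier:
        if mol is None or mol.GetNumConformers() == 0:
            continue
        conf = mol.GetConformer()
        ens.conformers.append(Conformer(
            elements=tuple(a.GetSymbol() for a in mol.GetAtoms()),
            coords=np.array(conf.GetPositions(), dtype=float),
        ))
    if not ens.conformers:
        raise DomainError(f"{path}: no 3D conformers found")
    return ens


def read_ensemble_pdb(path: Union[str, Path], compound_id: Optional[str] = None) -> ConformerEnsemble:
    """Read a multi-model PDB file (e.g. a cleaned MD trajectory) as an
    ensemble; all models must share one atom list."""
    import biotite.structure.io.pdb as pdb

    path = Path(path)
    stack = pdb.PDBFile.read(str(path)).get_structure()
    ens = ConformerEnsemble(compound_id=compound_id or path.stem)
    elements = tuple(e.capitalize() for e in stack.element)
    for model in range(stack.stack_depth()):
        ens.conformers.append(Conformer(elements=elements,
                                        coords=np.array(stack.coord[model], dtype=float)))
    return ens
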