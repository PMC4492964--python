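"""Discriminant analysis of principal components on allele-dosage profiles.

Each lineage is encoded as a vector of per-allele dosages (0, 0.5, 1);
missing calls are imputed with the column mean. After column centering,
principal axes come from an SVD, and linear discriminant axes are
computed on the retained PC scores between the supplied groups. The
number of retained PCs defaults to the floor of one-third of the number
of lineages.

Discriminant axes are scaled so the pooled within-group variance along
each axis is 1, so distances between group means read directly in
within-group standard deviations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import linalg

from .genotype import MISSING, GenotypeMatrix


def retain_pcs(n_mll: int, fraction: float = 1.0 / 3.0) -> int:
    """PCs to retain: ``floor(n_mll * fraction)``, at least 1."""
    if n_mll < 3:
        raise ValueError("need at least 3 lineages to apply the retention rule")
    return max(1, math.floor(n_mll * fraction))


def dosage_matrix(matrix: GenotypeMatrix) -> tuple[np.ndarray, list[tuple[str, int]]]:
    """(n_samples, n_allele_columns) dosages in 0/0.5/1; NaN = missing."""
    arr = matrix.allele_array()
    cols: list[tuple[str, int]] = []
    blocks: list[np.ndarray] = []
    for j, lid in enumerate(matrix.locus_ids):
        calls = arr[:, j, :]
        present = calls[:, 0] > MISSING
        alleles = np.unique(calls[present])
        block = np.full((arr.shape[0], alleles.size), np.nan)
        for ai, a in enumerate(alleles):
            block[present, ai] = (calls[present] == a).sum(axis=1) / 2.0
        blocks.append(block)
        cols.extend((lid, int(a)) for a in alleles)
    return np.hstack(blocks), cols


@dataclass
class _Transform:
    """Dosage-space -> discriminant-space affine map fitted on training rows."""

    impute: np.ndarray  # column means used to fill NaN
    center: np.ndarray  # column means subtracted after imputation
    pc_rotation: np.ndarray  # (n_cols, n_pcs)
    score_center: np.ndarray  # (n_pcs,)
    axes: np.ndarray  # (n_pcs, n_axes)
    signs: np.ndarray  # (n_axes,)

    def __call__(self, dosage_rows: np.ndarray) -> np.ndarray:
        filled = np.where(np.isnan(dosage_rows), self.impute[None, :], dosage_rows)
        scores = (filled - self.center[None, :]) @ self.pc_rotation
        return ((scores - self.score_center[None, :]) @ self.axes) * self.signs


@dataclass
class DAPCResult:
    coords: np.ndarray  # (n, n_axes)
    sample_ids: list[str]
    groups: list[str]
    group_labels: list[str]
    centroids: np.ndarray  # (n_groups, n_axes)
    eigenvalues: np.ndarray
    n_pcs: int
    pca_var_explained: np.ndarray
    warnings: list[str]
    transform: _Transform = field(repr=False, default=None)

    def predict_group(self, coord: np.ndarray) -> str:
        d = np.linalg.norm(self.centroids - coord[None, :], axis=1)
        return self.group_labels[int(d.argmin())]


def _resolve_labels(sample_ids, groups) -> list[str]:
    if groups is None:
        raise ValueError("groups required")
    if isinstance(groups, Mapping):
        return [groups[sid] for sid in sample_ids]
    labels = list(groups)
    if len(labels) != len(sample_ids):
        raise ValueError("groups length must match sample count")
    return labels


def _fit_core(
    D: np.ndarray, labels: list[str], n_pcs: int, ridge: float
) -> tuple[DAPCResult, list[str], np.ndarray]:
    n = D.shape[0]
    uniq = list(dict.fromkeys(labels))
    y = np.array([uniq.index(l) for l in labels])

    impute = np.nanmean(D, axis=0)
    impute = np.where(np.isnan(impute), 0.0, impute)
    filled = np.where(np.isnan(D), impute[None, :], D)
    center = filled.mean(axis=0)
    centered = filled - center
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    var = s**2
    explained = var / var.sum() if var.sum() > 0 else var
    rotation = vt[:n_pcs].T
    scores = centered @ rotation
    p = scores.shape[1]

    warn_list: list[str] = []
    overall = scores.mean(axis=0)
    sw = np.zeros((p, p))
    sb = np.zeros((p, p))
    for gi in range(len(uniq)):
        sub = scores[y == gi]
        mg = sub.mean(axis=0)
        dev = sub - mg
        sw += dev.T @ dev
        diff = (mg - overall)[:, None]
        sb += sub.shape[0] * (diff @ diff.T)
    sw /= n
    sb /= n

    cond = np.linalg.cond(sw)
    if not np.isfinite(cond) or cond > 1e10:
        bump = ridge * max(np.trace(sw) / p, 1.0)
        sw = sw + bump * np.eye(p)
        warn_list.append("singular within-group scatter; ridge regularization applied")
        warnings.warn(warn_list[-1])

    eigval, eigvec = linalg.eigh(sb, sw)  # ascending; vectors Sw-normalized
    order = np.argsort(eigval)[::-1]
    n_axes = min(len(uniq) - 1, p)
    axes = eigvec[:, order[:n_axes]]
    eigval = eigval[order[:n_axes]]

    coords = (scores - overall) @ axes
    # sign convention: first group's centroid non-positive on each axis
    signs = np.ones(n_axes)
    for a in range(n_axes):
        if coords[y == 0, a].mean() > 0:
            signs[a] = -1.0
    coords = coords * signs
    centroids = np.vstack([coords[y == gi].mean(axis=0) for gi in range(len(uniq))])

    result = DAPCResult(
        coords=coords,
        sample_ids=[],
        groups=labels,
        group_labels=uniq,
        centroids=centroids,
        eigenvalues=eigval,
        n_pcs=n_pcs,
        pca_var_explained=explained,
        warnings=warn_list,
        transform=_Transform(
            impute=impute,
            center=center,
            pc_rotation=rotation,
            score_center=overall,
            axes=axes,
            signs=signs,
        ),
    )
    return result, uniq, y


def dapc_fit(
    matrix: GenotypeMatrix,
    groups: Mapping[str, str] | Sequence[str] | None = None,
    n_pcs: int | None = None,
    ridge: float = 1e-8,
) -> DAPCResult:
    """Fit DAPC; returns per-sample discriminant coordinates.

    ``groups`` maps sample id -> group label (or is a per-sample label
    sequence); defaults to the mito-type labels. With g groups and p
    retained PCs, ``min(g - 1, p)`` discriminant axes are produced.
    """
    sample_ids = matrix.sample_ids
    labels = (
        [s.mito_type for s in matrix.samples]
        if groups is None
        else _resolve_labels(sample_ids, groups)
    )
    if len(set(labels)) < 2:
        raise ValueError("DAPC needs at least two groups")
    n = len(sample_ids)
    if n_pcs is None:
        n_pcs = retain_pcs(n)
    if not 1 <= n_pcs < n:
        raise ValueError(f"n_pcs must be in [1, {n - 1}]")

    D, _ = dosage_matrix(matrix)
    result, _, _ = _fit_core(D, labels, n_pcs, ridge)
    result.sample_ids = list(sample_ids)
    return result


def loo_accuracy(
    matrix: GenotypeMatrix,
    groups: Mapping[str, str] | Sequence[str] | None = None,
    n_pcs: int | None = None,
) -> float:
    """Leave-one-out reassignment accuracy by nearest group centroid.

    For each sample the whole pipeline (imputation, centering, PCA, LDA)
    is refitted on the remaining samples; the held-out sample is then
    projected and assigned to the nearest centroid.
    """
    sample_ids = matrix.sample_ids
    labels = (
        [s.mito_type for s in matrix.samples]
        if groups is None
        else _resolve_labels(sample_ids, groups)
    )
    n = len(sample_ids)
    if n_pcs is None:
        n_pcs = retain_pcs(n)
    n_pcs = min(n_pcs, n - 2)

    D, _ = dosage_matrix(matrix)  # fixed encoding; parameters fitted per fold
    hits = 0
    for i in range(n):
        keep = [j for j in range(n) if j != i]
        train_labels = [labels[j] for j in keep]
        if len(set(train_labels)) < 2:
            continue
        fit, _, _ = _fit_core(D[keep], train_labels, n_pcs, ridge=1e-8)
        coord = fit.transform(D[i : i + 1])[0]
        if fit.predict_group(coord) == labels[i]:
            hits += 1
    return hits / n


def write_dapc_tsv(result: DAPCResult, path) -> None:
    n_axes = result.coords.shape[1]
    lines = ["sample_id\tgroup\t" + "\t".join(f"LD{a + 1}" for a in range(n_axes))]
    for sid, grp, row in zip(result.sample_ids, result.groups, result.coords):
        lines.append(sid + "\t" + grp + "\t" + "\t".join(f"{v:.6f}" for v in row))
    Path(path).write_text("\n".join(lines) + "\n")
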