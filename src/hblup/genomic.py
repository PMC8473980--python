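"""Genotype QC and the genomic relationship matrix G.

G follows VanRaden's first method, ``G = ZZ' / (2 Σ p_j (1 − p_j))`` with
``Z = M − 2P``, computed from the observed allele frequencies of the
genotyped sample.  ``tune_G`` rescales G so its mean diagonal and mean
overall entry match those of the pedigree block A22 among the genotyped
individuals, and ``blend_G`` takes the usual convex combination with A22 to
guarantee invertibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .relmat import RelationshipMatrix

_RAW_LEADING = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


@dataclass
class MarkerMatrix:
    """Individuals × markers genotype scores in {0, 1, 2} with missingness.

    ``scores`` is a float array with ``np.nan`` for missing calls.  After
    :func:`qc_filter` there are no missing entries and ``freq`` holds the
    per-marker alternative-allele frequency.
    """

    ids: list[str]
    markers: list[str]
    scores: np.ndarray
    freq: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.ids), len(self.markers)):
            raise ValueError("scores shape does not match ids × markers")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate individual id in genotype data")
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("duplicate marker name in genotype data")
        valid = np.isnan(self.scores) | np.isin(self.scores, (0.0, 1.0, 2.0))
        # post-QC matrices carry imputed fractional scores; only validate
        # range there
        if self.freq is None and not valid.all():
            i, j = np.argwhere(~valid)[0]
            raise ValueError(
                f"invalid genotype score {self.scores[i, j]!r} for individual "
                f"{self.ids[i]!r}, marker {self.markers[j]!r}")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def m(self) -> int:
        return len(self.markers)

    def subset_ids(self, ids: list[str]) -> "MarkerMatrix":
        index = {iid: k for k, iid in enumerate(self.ids)}
        idx = [index[i] for i in ids]
        return MarkerMatrix(list(ids), list(self.markers),
                            self.scores[idx], self.freq)


def read_genotypes(path) -> MarkerMatrix:
    """Read a genotype table in either plain TSV or PLINK ``.raw`` dialect.

    Plain TSV: first column the individual id, remaining columns markers,
    entries 0/1/2/NA.  PLINK ``.raw``: whitespace-separated with leading
    FID IID PAT MAT SEX PHENOTYPE columns; IID is used as the id.
    """
    with open(path) as fh:
        header = fh.readline().split()
    body = header[len(_RAW_LEADING):] \
        if header[: len(_RAW_LEADING)] == _RAW_LEADING else header[1:]
    if len(set(body)) != len(body):
        dup = next(m for m in body if body.count(m) > 1)
        raise ValueError(f"duplicate marker name in {path}: {dup!r}")
    if header[: len(_RAW_LEADING)] == _RAW_LEADING:
        df = pd.read_csv(path, sep=r"\s+")
        ids = df["IID"].astype(str).tolist()
        marker_cols = df.columns[len(_RAW_LEADING):]
        scores = df[marker_cols].to_numpy(dtype=float)
        markers = [c for c in marker_cols]
    else:
        df = pd.read_csv(path, sep="\t")
        ids = df.iloc[:, 0].astype(str).tolist()
        markers = list(df.columns[1:])
        raw = df.iloc[:, 1:]
        try:
            scores = raw.apply(pd.to_numeric, errors="raise").to_numpy(dtype=float)
        except (ValueError, TypeError) as exc:
            raise ValueError(f"non-numeric genotype token in {path}: {exc}") from exc
    return MarkerMatrix(ids, markers, scores)


def qc_filter(mm: MarkerMatrix, maf_threshold: float = 0.05,
              report: list | None = None) -> MarkerMatrix:
    """MAF filter and mean imputation.

    Markers with minor allele frequency (from non-missing calls) below
    ``maf_threshold`` are removed; remaining missing scores are imputed to
    the marker mean ``2 p_j``.  If ``report`` is a list, one
    ``(marker, p, status, reason)`` tuple per input marker is appended.
    """
    obs = ~np.isnan(mm.scores)
    n_obs = obs.sum(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.where(n_obs > 0,
                     np.nansum(mm.scores, axis=0) / (2.0 * np.maximum(n_obs, 1)),
                     np.nan)
    maf = np.minimum(p, 1.0 - p)
    keep = (n_obs > 0) & (maf >= maf_threshold)
    if report is not None:
        for j, name in enumerate(mm.markers):
            if n_obs[j] == 0:
                report.append((name, float("nan"), "removed", "all missing"))
            elif maf[j] < maf_threshold:
                report.append((name, float(p[j]), "removed",
                               f"MAF {maf[j]:.4f} < {maf_threshold}"))
            else:
                report.append((name, float(p[j]), "kept", ""))
    if not keep.any():
        raise ValueError("no informative markers after MAF filtering")
    scores = mm.scores[:, keep].copy()
    pk = p[keep]
    miss = np.isnan(scores)
    if miss.any():
        fill = np.broadcast_to(2.0 * pk, scores.shape)
        scores[miss] = fill[miss]
    kept = [m for m, k in zip(mm.markers, keep) if k]
    return MarkerMatrix(list(mm.ids), kept, scores, freq=pk)


def compute_G_vanraden1(mm: MarkerMatrix) -> RelationshipMatrix:
    """Genomic relationship matrix, VanRaden method 1."""
    if mm.freq is None:
        raise ValueError("run qc_filter first (frequencies missing)")
    p = mm.freq
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0.0:
        raise ValueError("all markers monomorphic: zero VanRaden denominator")
    Z = mm.scores - 2.0 * p[None, :]
    G = (Z @ Z.T) / denom
    G = 0.5 * (G + G.T)
    return RelationshipMatrix(list(mm.ids), G, "G")


@dataclass
class TuningCoefficients:
    """Intercept/slope rescaling G onto the A22 scale (``Ga = a + bG``)."""

    a: float
    b: float


def tune_G(G: RelationshipMatrix, A22: RelationshipMatrix
           ) -> tuple[RelationshipMatrix, TuningCoefficients]:
    """Rescale G so its first moments match A22.

    Solves ``a + b·mean(diag G) = mean(diag A22)`` and
    ``a + b·mean(G) = mean(A22)`` where the second pair of means runs over
    all n² entries, then applies ``Ga = a + bG`` elementwise.
    """
    if G.ids != A22.ids:
        raise ValueError("G and A22 must share ids and order")
    gd, gm = float(np.mean(np.diag(G.values))), float(np.mean(G.values))
    ad, am = float(np.mean(np.diag(A22.values))), float(np.mean(A22.values))
    det = gd - gm
    if abs(det) < 1e-12:
        raise ValueError("degenerate G, cannot tune (mean diag equals overall mean)")
    b = (ad - am) / det
    a = ad - b * gd
    Ga = RelationshipMatrix(list(G.ids), a + b * G.values, "Ga")
    return Ga, TuningCoefficients(a=a, b=b)


def blend_G(Ga: RelationshipMatrix, A22: RelationshipMatrix,
            w: float = 0.95) -> RelationshipMatrix:
    """Blend the tuned genomic matrix with A22: ``Gw = w·Ga + (1−w)·A22``."""
    if not 0.0 <= w <= 1.0:
        raise ValueError(f"blend weight must be in [0, 1], got {w}")
    if Ga.ids != A22.ids:
        raise ValueError("Ga and A22 must share ids and order")
    return RelationshipMatrix(list(Ga.ids),
                              w * Ga.values + (1.0 - w) * A22.values, "Gw")


def write_qc_report(report: list, path) -> None:
    pd.DataFrame(report, columns=["marker", "p", "status", "reason"]).to_csv(
        path, sep="\t", index=False)
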