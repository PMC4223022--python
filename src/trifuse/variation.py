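"""Inter- and intra-observer delineation-variation analytics.

Three complementary measures of how much observers disagree about one
structure:

* **COV** — coefficient of variation of the delineated volumes, the sample
  standard deviation (n-1 denominator) divided by the mean.  A pure volume
  measure, blind to shape.
* **ADSC** statistics — mean and SD over observers of the average distance
  between surface and centroid (see :mod:`trifuse.surfaces`), a global shape
  measure.
* **SD_local** — the per-vertex standard deviation of the perpendicular
  distances from the 50%-coverage *median surface* to each observer surface,
  measured along the median-surface vertex normals (signed, outward positive).
  This maps *where* on the structure observers disagree.  For reporting it is
  averaged over the eight octants of a coordinate system centered at the mean
  of the observer-mask centroids, and over all vertices.

Differences between delineation schemes are assessed with the classic paired
two-tailed t test (df = n-1, 95% confidence interval).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import trimesh
from scipy import stats

from .errors import EmptyInputError, GeometryError, InputError, ParameterError
from .masks import MaskSet
from .surfaces import extract_surface, mask_centroid, ray_mesh_signed_offsets
from .volumes import GTVMask

__all__ = [
    "CovReport",
    "PairedTestResult",
    "DistanceCap",
    "MedianSurfaceResult",
    "VariationReport",
    "cov",
    "paired_t_two_tailed",
    "coverage_volume",
    "median_surface",
    "signed_normal_distance",
    "sd_local",
    "octant_labels",
    "aggregate_sd_local",
    "analyze_median_surface",
    "variation_report",
]


# ---------------------------------------------------------------------------
# Scalar statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CovReport:
    """Coefficient of variation of a set of scalars (volumes, metrics...)."""

    values: tuple[float, ...]
    mean: float
    sd: float
    cov: float
    undefined: bool = False  # mean == 0: COV has no meaning


def cov(values: Sequence[float], ddof: int = 1) -> CovReport:
    """COV = sample SD / mean.

    ``ddof=1`` (the n-1 sample convention) is the default and the convention
    used throughout the reporting tables; ``ddof=0`` is accepted only so the
    two conventions can be compared.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < 2:
        raise InputError(f"COV needs at least 2 values, got {vals.size}")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=ddof))
    if mean == 0.0:
        return CovReport(tuple(vals), mean, sd, float("nan"), undefined=True)
    return CovReport(tuple(vals), mean, sd, sd / mean)


@dataclass(frozen=True)
class PairedTestResult:
    """Classic paired two-tailed t test on differences d = a - b."""

    n: int
    mean_diff: float
    t: float
    df: int
    p: float | None
    ci_low: float
    ci_high: float
    degenerate: bool = False  # zero-variance differences: no p-value exists

    @property
    def significant(self) -> bool:
        return self.p is not None and self.p < 0.05


def paired_t_two_tailed(
    a: Sequence[float], b: Sequence[float], confidence: float = 0.95
) -> PairedTestResult:
    """Paired t on ``d = a - b`` with a two-sided p and a symmetric CI.

    Zero-variance differences (including a == b) are reported as degenerate
    with ``p=None`` rather than raising or faking significance.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("paired test needs two equal-length 1D sequences")
    n = x.size
    if n < 2:
        raise InputError(f"paired test needs n >= 2 pairs, got {n}")
    d = x - y
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    df = n - 1
    if sd_d == 0.0:
        return PairedTestResult(
            n, mean_d, float("nan"), df, None, mean_d, mean_d, degenerate=True
        )
    res = stats.ttest_rel(x, y)
    se = sd_d / np.sqrt(n)
    half = stats.t.ppf(0.5 + confidence / 2.0, df) * se
    return PairedTestResult(
        n=n,
        mean_diff=mean_d,
        t=float(res.statistic),
        df=df,
        p=float(res.pvalue),
        ci_low=mean_d - half,
        ci_high=mean_d + half,
    )


# ---------------------------------------------------------------------------
# Median surface (coverage probability) and SD_local
# ---------------------------------------------------------------------------

def _as_maskset(masks: MaskSet | Sequence[GTVMask]) -> MaskSet:
    if isinstance(masks, MaskSet):
        return masks
    return MaskSet(list(masks))


def coverage_volume(
    masks: MaskSet | Sequence[GTVMask], threshold: float = 0.5
) -> GTVMask:
    """Voxels covered by at least ``threshold`` of the observer masks.

    A voxel is kept iff (number of masks containing it) / N >= threshold, ties
    included — with three observers and the default 0.5 this is the majority
    region, whose boundary is the median surface.
    """
    ms = _as_maskset(masks)
    if len(ms) < 2:
        raise InputError("coverage needs at least 2 masks")
    if not 0.0 < threshold <= 1.0:
        raise ParameterError(f"threshold must be in (0, 1], got {threshold}")
    counts = ms.stack().sum(axis=0)
    keep = counts >= threshold * len(ms) - 1e-12
    return GTVMask(data=keep, grid=ms.grid)


def median_surface(masks: MaskSet | Sequence[GTVMask]) -> trimesh.Trimesh:
    """Marching-cubes mesh of the 50% coverage volume, outward normals."""
    cov_mask = coverage_volume(masks, threshold=0.5)
    if cov_mask.is_empty():
        raise EmptyInputError("the 50% coverage volume is empty")
    return extract_surface(cov_mask)


@dataclass(frozen=True)
class DistanceCap:
    """Maximum search distance (mm) along the normal for surface distances."""

    s_max: float = 50.0

    def __post_init__(self) -> None:
        if not self.s_max > 0:
            raise ParameterError("s_max must be positive")


def _signed_distances_to_mesh(
    median_mesh: trimesh.Trimesh,
    observer_mesh: trimesh.Trimesh,
    cap: DistanceCap,
) -> tuple[np.ndarray, np.ndarray]:
    """Signed normal distances (mm) from every median-mesh vertex to one
    observer mesh; returns (distances, fallback_flags).

    Primary rule: smallest-|s| intersection of the bidirectional ray
    ``v + s*n`` (n the outward unit vertex normal) with the observer mesh,
    |s| <= cap.  Sign: positive where the observer surface lies outward of the
    median surface.  Where the ray misses within the cap, fall back to the
    nearest point on the observer mesh, signed by the local orientation of the
    observer surface (its outward normal at the nearest triangle), and flag it.
    """
    verts = median_mesh.vertices
    normals = np.asarray(median_mesh.vertex_normals, dtype=float)
    bad = np.linalg.norm(normals, axis=1) < 1e-12
    if bad.any():
        raise GeometryError(f"{bad.sum()} median-surface vertices have degenerate normals")

    s = ray_mesh_signed_offsets(verts, normals, observer_mesh, cap.s_max)
    fallback = np.isnan(s)
    if fallback.any():
        idx = np.nonzero(fallback)[0]
        tri = observer_mesh.triangles
        tri_normals = observer_mesh.face_normals
        for i in idx:
            p = verts[i]
            pts = trimesh.triangles.closest_point(tri, np.tile(p, (len(tri), 1)))
            dist = np.linalg.norm(pts - p, axis=1)
            j = int(np.argmin(dist))
            # observer surface outward of p (p inside observer) -> positive
            outward = np.dot(pts[j] - p, tri_normals[j]) > 0
            s[i] = dist[j] if outward else -dist[j]
    return s, fallback


def signed_normal_distance(
    median_mesh: trimesh.Trimesh,
    vertex_index: int,
    observer_mesh: trimesh.Trimesh,
    cap: DistanceCap = DistanceCap(),
) -> float:
    """Signed perpendicular distance (cm) from one median-surface vertex to an
    observer surface, along the vertex normal (positive outward)."""
    n = np.asarray(median_mesh.vertex_normals[vertex_index], dtype=float)
    if np.linalg.norm(n) < 1e-12:
        raise GeometryError(f"vertex {vertex_index} has a degenerate normal")
    view = trimesh.Trimesh(
        vertices=median_mesh.vertices[[vertex_index]], process=False
    )
    view.vertex_normals = n[None, :]
    s, _ = _signed_distances_to_mesh(view, observer_mesh, cap)
    return float(s[0] / 10.0)


@dataclass
class MedianSurfaceResult:
    """Per-vertex local-variation result on the median surface.

    ``distances_cm`` has shape (n_vertices, n_observers); ``sd_local_cm`` is
    the sample SD (n-1) across observers at each vertex.  ``octant_label``
    (1..8) partitions vertices by the octants of axes through the mean
    observer centroid; filled by :func:`octant_labels`.
    """

    median_mesh: trimesh.Trimesh
    distances_cm: np.ndarray
    sd_local_cm: np.ndarray
    fallback_count: int = 0
    octant_label: np.ndarray | None = None
    octant_mean_cm: np.ndarray | None = None
    overall_mean_cm: float | None = None


def sd_local(
    median_mesh: trimesh.Trimesh,
    observer_meshes: Sequence[trimesh.Trimesh],
    cap: DistanceCap = DistanceCap(),
    signed: bool = True,
) -> MedianSurfaceResult:
    """Per-vertex SD of the normal distances to each observer surface.

    ``signed=True`` (default) uses signed outward distances, following the
    coverage-probability methodology; ``signed=False`` uses |distance|.  The
    per-vertex values are attached to the mesh as vertex attribute
    ``"sd_local"`` (cm) for export and color-wash rendering.
    """
    if len(observer_meshes) < 2:
        raise InputError("SD_local needs at least 2 observer surfaces")
    cols = []
    n_fallback = 0
    for obs in observer_meshes:
        s_mm, fb = _signed_distances_to_mesh(median_mesh, obs, cap)
        n_fallback += int(fb.sum())
        cols.append(s_mm / 10.0)
    distances = np.column_stack(cols)
    if not signed:
        distances = np.abs(distances)
    sd = distances.std(axis=1, ddof=1)
    median_mesh.vertex_attributes["sd_local"] = sd
    return MedianSurfaceResult(
        median_mesh=median_mesh,
        distances_cm=distances,
        sd_local_cm=sd,
        fallback_count=n_fallback,
    )


def octant_labels(
    median_mesh: trimesh.Trimesh, observer_masks: MaskSet | Sequence[GTVMask]
) -> np.ndarray:
    """Octant label (1..8) per median-surface vertex.

    The octants are those of world axes translated to the mean of the observer
    mask centroids; the label is ``1 + [x<Ox] + 2[y<Oy] + 4[z<Oz]`` with
    boundary coordinates (exactly equal to the origin) on the ">=" side, so
    label 1 is the (+,+,+) octant.
    """
    ms = _as_maskset(observer_masks)
    origin = np.mean([mask_centroid(m) for m in ms], axis=0)
    v = median_mesh.vertices
    return (
        1
        + (v[:, 0] < origin[0]).astype(int)
        + 2 * (v[:, 1] < origin[1]).astype(int)
        + 4 * (v[:, 2] < origin[2]).astype(int)
    )


def aggregate_sd_local(result: MedianSurfaceResult) -> MedianSurfaceResult:
    """Fill octant means (8 values, NaN where an octant holds no vertex) and
    the overall vertex mean of SD_local, in cm.

    The overall mean is over *all* vertices, independent of octant occupancy.
    """
    if result.octant_label is None:
        raise InputError("octant labels missing: call octant_labels first")
    means = np.full(8, np.nan)
    for k in range(1, 9):
        sel = result.octant_label == k
        if sel.any():
            means[k - 1] = result.sd_local_cm[sel].mean()
    result.octant_mean_cm = means
    result.overall_mean_cm = float(result.sd_local_cm.mean())
    return result


def analyze_median_surface(
    masks: MaskSet | Sequence[GTVMask],
    cap: DistanceCap = DistanceCap(),
    signed: bool = True,
) -> MedianSurfaceResult:
    """Full local-variation chain: median surface -> observer surfaces ->
    per-vertex SD_local -> octant and overall means."""
    ms = _as_maskset(masks)
    med = median_surface(ms)
    obs_meshes = [extract_surface(m) for m in ms]
    result = sd_local(med, obs_meshes, cap=cap, signed=signed)
    result.octant_label = octant_labels(med, ms)
    return aggregate_sd_local(result)


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------

@dataclass
class VariationReport:
    """Tabular summary across patients, observers and delineation schemes."""

    volume_table: pd.DataFrame
    adsc_table: pd.DataFrame
    sdlocal_table: pd.DataFrame | None
    tests: pd.DataFrame

    def to_csv(self, path) -> None:
        """Write all sections into one CSV file, blank-line separated."""
        with open(path, "w") as fh:
            for title, table in (
                ("# volumes", self.volume_table),
                ("# adsc", self.adsc_table),
                ("# sd_local", self.sdlocal_table),
                ("# paired_tests", self.tests),
            ):
                if table is None:
                    continue
                fh.write(title + "\n")
                table.to_csv(fh, index=False, lineterminator="\n")
                fh.write("\n")


def _per_patient_stats(
    by_scheme: Mapping[str, Mapping[str, Sequence[float]]], metric: str
) -> pd.DataFrame:
    rows = []
    for scheme, patients in by_scheme.items():
        for patient, values in patients.items():
            vals = list(map(float, values))
            row = {
                "scheme": scheme,
                "patient": patient,
                "n_observers": len(vals),
                "mean": np.mean(vals),
            }
            if len(vals) >= 2:
                r = cov(vals)
                row["sd"] = r.sd
                row["cov"] = r.cov
                row["computable"] = not r.undefined
            else:  # single observer: spread statistics do not exist
                row["sd"] = np.nan
                row["cov"] = np.nan
                row["computable"] = False
            row["metric"] = metric
            rows.append(row)
    return pd.DataFrame(rows)


def variation_report(
    volumes_by_scheme: Mapping[str, Mapping[str, Sequence[float]]],
    adsc_by_scheme: Mapping[str, Mapping[str, Sequence[float]]] | None = None,
    masks_by_scheme: Mapping[str, Mapping[str, MaskSet]] | None = None,
    cap: DistanceCap = DistanceCap(),
) -> VariationReport:
    """Assemble the full variation report.

    ``volumes_by_scheme[scheme][patient]`` are per-observer volumes (cm^3);
    ``adsc_by_scheme`` likewise for ADSC (cm); ``masks_by_scheme`` optionally
    provides the masks for the SD_local octant table.  Schemes must cover the
    same patients; with exactly two schemes, paired t tests across schemes are
    run on per-patient COV and ADSC-SD values.
    """
    schemes = list(volumes_by_scheme)
    patient_sets = {s: tuple(sorted(volumes_by_scheme[s])) for s in schemes}
    if len(set(patient_sets.values())) != 1:
        raise InputError(f"schemes cover different patients: {patient_sets}")

    volume_table = _per_patient_stats(volumes_by_scheme, "volume_cm3")
    adsc_table = (
        _per_patient_stats(adsc_by_scheme, "adsc_cm")
        if adsc_by_scheme
        else pd.DataFrame()
    )

    sdlocal_table = None
    if masks_by_scheme:
        rows = []
        for scheme, patients in masks_by_scheme.items():
            for patient, ms in patients.items():
                res = analyze_median_surface(ms, cap=cap)
                row = {"scheme": scheme, "patient": patient}
                for k in range(8):
                    row[f"octant_{k + 1}"] = res.octant_mean_cm[k]
                row["overall"] = res.overall_mean_cm
                row["fallback_count"] = res.fallback_count
                rows.append(row)
        sdlocal_table = pd.DataFrame(rows)

    test_rows = []
    if len(schemes) == 2:
        s1, s2 = schemes
        pats = patient_sets[s1]

        def run_test(name: str, table: pd.DataFrame, column: str) -> None:
            if table.empty:
                return
            piv = table.pivot(index="patient", columns="scheme", values=column)
            a = piv.loc[list(pats), s1].to_numpy()
            b = piv.loc[list(pats), s2].to_numpy()
            if np.isnan(a).any() or np.isnan(b).any():
                return
            r = paired_t_two_tailed(a, b)
            test_rows.append(
                {
                    "comparison": f"{name}: {s1} vs {s2}",
                    "n": r.n,
                    "mean_diff": r.mean_diff,
                    "t": r.t,
                    "df": r.df,
                    "p": r.p,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "degenerate": r.degenerate,
                }
            )

        run_test("volume COV", volume_table, "cov")
        run_test("ADSC SD", adsc_table, "sd")

    return VariationReport(
        volume_table=volume_table,
        adsc_table=adsc_table,
        sdlocal_table=sdlocal_table,
        tests=pd.DataFrame(test_rows),
    )
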