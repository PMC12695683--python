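"""Seeded synthetic DICOM-RT phantom cohorts.

Generates, per patient, a geometric phantom on a small isotropic lattice:
an RTSTRUCT of organ-at-risk primitives (spheres / ellipsoids / cylinders),
a treatment-beam RTDOSE (sigmoid distance falloff from a target centre, so
per-ROI mean doses have semi-analytic expectations), and a per-fraction
MV-CBCT imaging RTDOSE (low-magnitude broad field proportional to MU with a
mild anterior-posterior gradient), plus a cohort manifest CSV with
demographics spanning three age strata.

Three site templates (breast / pelvic / head & neck) are calibrated so the
course-total mean doses land in the magnitude ranges typical of those
treatments (ipsilateral lung around 19 Gy in breast courses, rectum near
49 Gy in pelvic courses, parotids near 25-28 Gy in head & neck courses).
All randomness derives from per-patient substreams of one seed, and every
DICOM write is deterministic, so regeneration is byte-identical.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dvh import DifferentialDVH
from .errors import ParameterError
from .grids import ROI, DoseGrid, StructureSet
from .rtio import deterministic_uid, write_rtdose, write_rtstruct

#: default phantom lattice: 64^3 voxels at 2.5 mm (160 mm extent), small
#: enough for seconds-scale end-to-end runs while keeping organ primitives
#: tens of voxels across
DEFAULT_GRID_SHAPE = (64, 64, 64)
DEFAULT_SPACING_MM = 2.5

#: imaging dose per monitor unit at isocentre (Gy/MU); 5 MU -> 3 cGy per
#: fraction, in the several-cGy-per-fraction range typical of MV-CBCT
DEFAULT_IMAGING_DOSE_PER_MU = 0.006

#: relative strength of the anterior-posterior gradient of the imaging field
IMAGING_AP_GRADIENT = 0.15

SITE_FRACTION_DEFAULTS = {"breast": 25, "pelvic": 28, "head_neck": 35}

#: inclusive integer age ranges per stratum: [18,40), [40,60], (60,85]
AGE_STRATA_BOUNDS = ((18, 39), (40, 60), (61, 85))


@dataclass(frozen=True)
class ShapeSpec:
    """One ROI primitive: sphere, ellipsoid or z-axis cylinder."""

    name: str
    kind: str  # "sphere" | "ellipsoid" | "cylinder"
    center: tuple  # (x, y, z) mm
    size: tuple  # sphere: (r,); ellipsoid: (ax, ay, az); cylinder: (r, half_len)

    def contains(self, x, y, z) -> np.ndarray:
        cx, cy, cz = self.center
        if self.kind == "sphere":
            (r,) = self.size
            return (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= r**2
        if self.kind == "ellipsoid":
            ax, ay, az = self.size
            return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0
        if self.kind == "cylinder":
            r, hl = self.size
            return ((x - cx) ** 2 + (y - cy) ** 2 <= r**2) & (np.abs(z - cz) <= hl)
        raise ParameterError(f"unknown primitive kind {self.kind!r}")

    def cross_section(self, z: float):
        """Semi-axes (ax, ay) of the axial cross-section at height z, or None."""
        cx, cy, cz = self.center
        if self.kind == "sphere":
            (r,) = self.size
            d2 = r**2 - (z - cz) ** 2
            return (np.sqrt(d2), np.sqrt(d2)) if d2 > 0 else None
        if self.kind == "ellipsoid":
            ax, ay, az = self.size
            f = 1.0 - ((z - cz) / az) ** 2
            return (ax * np.sqrt(f), ay * np.sqrt(f)) if f > 0 else None
        if self.kind == "cylinder":
            r, hl = self.size
            return (r, r) if abs(z - cz) <= hl else None
        raise ParameterError(f"unknown primitive kind {self.kind!r}")


@dataclass(frozen=True)
class SiteTemplate:
    """Geometry and dose-scale targets for one treatment site."""

    site: str
    roi_specs: tuple  # of ShapeSpec
    target_center: tuple  # treatment field centre (x, y, z) mm
    prescription_gy: float
    falloff_radius_mm: float  # sigmoid midpoint distance
    falloff_width_mm: float  # sigmoid width
    site_fraction_default: int
    dose_scale_targets: dict  # roi -> (lo, hi) Gy course-total mean dose
    grid_shape: tuple = DEFAULT_GRID_SHAPE
    spacing_mm: float = DEFAULT_SPACING_MM
    mirror_by_laterality: bool = False
    scatter_frac: float = 0.0  # out-of-field tail, fraction of prescription
    scatter_len_mm: float = 60.0  # exponential length of the tail


@dataclass(frozen=True)
class CohortSpec:
    """Cohort-level generation parameters."""

    site: str
    n_patients: int
    seed: int
    age_proportions: tuple = (0.3, 0.4, 0.3)  # <40 / 40-60 / >60
    mu_reference: float = 5.0
    imaging_dose_per_mu: float = DEFAULT_IMAGING_DOSE_PER_MU
    noise: float = 0.08  # relative SD of per-patient dose-scale jitter

    def __post_init__(self):
        if self.n_patients < 1:
            raise ParameterError("n_patients must be >= 1")
        if abs(sum(self.age_proportions) - 1.0) > 1e-9:
            raise ParameterError("age stratum proportions must sum to 1")


def _grid_geometry(template: SiteTemplate):
    shape = template.grid_shape
    spacing = np.array([template.spacing_mm] * 3)
    # lattice centred on the patient origin
    origin = -spacing * (np.array(shape)[::-1] - 1) / 2.0
    return origin, spacing


# ---------------------------------------------------------------------------
# Site templates
# ---------------------------------------------------------------------------

def _breast_template() -> SiteTemplate:
    # calibrated so course-total means sit near tangent-field magnitudes:
    # ipsilateral lung ~19 Gy, heart ~7, contralateral structures ~3-4
    rois = (
        ShapeSpec("Lung_IPSI", "ellipsoid", (-36, -5, 0), (20, 26, 42)),
        ShapeSpec("Lung_CNTR", "ellipsoid", (33, 5, 0), (20, 28, 42)),
        ShapeSpec("Heart", "ellipsoid", (-4, 4, -8), (22, 20, 22)),
        ShapeSpec("Breast_CNTR", "ellipsoid", (38, -38, 0), (20, 18, 26)),
    )
    return SiteTemplate(
        site="breast",
        roi_specs=rois,
        target_center=(-52, -35, 0),
        prescription_gy=52.0,
        falloff_radius_mm=28.0,
        falloff_width_mm=11.0,
        site_fraction_default=25,
        dose_scale_targets={
            "Lung_IPSI": (13.0, 27.0),
            "Lung_CNTR": (2.0, 5.5),
            "Heart": (4.0, 9.5),
            "Breast_CNTR": (2.2, 5.8),
        },
        mirror_by_laterality=True,
        scatter_frac=0.11,
        scatter_len_mm=150.0,
    )


def _pelvic_template() -> SiteTemplate:
    # rectum abuts the target (course mean ~48 Gy); bladder ~35, bowel ~22
    rois = (
        ShapeSpec("Rectum", "cylinder", (0, 30, 0), (12, 28)),
        ShapeSpec("Bladder", "ellipsoid", (0, -13, 2), (24, 20, 22)),
        ShapeSpec("Bowel_Bag", "ellipsoid", (0, 4, 32), (42, 30, 22)),
    )
    return SiteTemplate(
        site="pelvic",
        roi_specs=rois,
        target_center=(0, 14, 0),
        prescription_gy=68.0,
        falloff_radius_mm=30.0,
        falloff_width_mm=9.0,
        site_fraction_default=28,
        dose_scale_targets={
            "Rectum": (33.0, 64.0),
            "Bladder": (24.0, 48.0),
            "Bowel_Bag": (14.0, 29.0),
        },
        scatter_frac=0.06,
        scatter_len_mm=90.0,
    )


def _head_neck_template() -> SiteTemplate:
    # parotids ~25 Gy, cord/brainstem ~15-16, optic nerves a few Gy
    rois = (
        ShapeSpec("Parotid_L", "ellipsoid", (-32, 8, 8), (12, 14, 16)),
        ShapeSpec("Parotid_R", "ellipsoid", (32, 8, 8), (12, 14, 16)),
        ShapeSpec("SpinalCord", "cylinder", (0, 39, -20), (5, 42)),
        ShapeSpec("Brainstem", "cylinder", (0, 26, 38), (8, 20)),
        ShapeSpec("OpticNerve_L", "ellipsoid", (-16, -18, 54), (4, 12, 4)),
        ShapeSpec("OpticNerve_R", "ellipsoid", (16, -18, 54), (4, 12, 4)),
    )
    return SiteTemplate(
        site="head_neck",
        roi_specs=rois,
        target_center=(0, 6, 0),
        prescription_gy=72.0,
        falloff_radius_mm=26.0,
        falloff_width_mm=10.0,
        site_fraction_default=35,
        dose_scale_targets={
            "Parotid_L": (17.0, 34.0),
            "Parotid_R": (17.0, 34.0),
            "SpinalCord": (10.0, 21.0),
            "Brainstem": (11.0, 22.0),
            "OpticNerve_L": (2.2, 6.6),
            "OpticNerve_R": (2.2, 6.6),
        },
        scatter_frac=0.05,
        scatter_len_mm=70.0,
    )


SITE_TEMPLATES = {
    "breast": _breast_template(),
    "pelvic": _pelvic_template(),
    "head_neck": _head_neck_template(),
}


# ---------------------------------------------------------------------------
# Per-patient generation
# ---------------------------------------------------------------------------

def _patient_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=(seed, index)))


def _mirror_x(pt):
    return (-pt[0], pt[1], pt[2])


def _effective_specs(template: SiteTemplate, laterality: str | None):
    """ROI primitives and target centre, mirrored in x for right-sided cases."""
    if not template.mirror_by_laterality or laterality != "right":
        return template.roi_specs, template.target_center
    specs = tuple(
        ShapeSpec(s.name, s.kind, _mirror_x(s.center), s.size) for s in template.roi_specs
    )
    return specs, _mirror_x(template.target_center)


def _contours_for(spec: ShapeSpec, z_centers: np.ndarray, n_vertices: int = 48):
    """Axial polygon contours of a primitive on the grid's slice planes."""
    contours = []
    theta = 2 * np.pi * np.arange(n_vertices) / n_vertices
    for z in z_centers:
        cs = spec.cross_section(float(z))
        if cs is None:
            continue
        ax, ay = cs
        if min(ax, ay) < 1e-6:
            continue
        pts = np.column_stack([
            spec.center[0] + ax * np.cos(theta),
            spec.center[1] + ay * np.sin(theta),
            np.full(n_vertices, z),
        ])
        contours.append(pts)
    return contours


def _treatment_field(template: SiteTemplate, origin, spacing, target_center,
                     scale: float) -> np.ndarray:
    nz, ny, nx = template.grid_shape
    x = origin[0] + spacing[0] * np.arange(nx)
    y = origin[1] + spacing[1] * np.arange(ny)
    z = origin[2] + spacing[2] * np.arange(nz)
    zz, yy, xx = np.meshgrid(z, y, x, indexing="ij")
    r = np.sqrt(
        (xx - target_center[0]) ** 2
        + (yy - target_center[1]) ** 2
        + (zz - target_center[2]) ** 2
    )
    dose = template.prescription_gy / (
        1.0 + np.exp((r - template.falloff_radius_mm) / template.falloff_width_mm)
    )
    # low out-of-field tail (head leakage / phantom scatter surrogate) so
    # distant organs see the few-Gy course totals typical of real plans
    if template.scatter_frac > 0:
        dose = dose + (
            template.prescription_gy
            * template.scatter_frac
            * np.exp(-r / template.scatter_len_mm)
        )
    return scale * dose


def _imaging_field(template: SiteTemplate, origin, spacing, per_fraction_iso_gy: float,
                   scale: float) -> np.ndarray:
    """Broad per-fraction imaging field with a mild anterior-posterior gradient."""
    nz, ny, nx = template.grid_shape
    y = origin[1] + spacing[1] * np.arange(ny)
    y_norm = (y - y.min()) / max(y.max() - y.min(), 1e-9) - 0.5  # [-0.5, 0.5]
    profile = 1.0 + IMAGING_AP_GRADIENT * y_norm
    field = np.broadcast_to(
        profile[None, :, None], (nz, ny, nx)
    ) * per_fraction_iso_gy
    return scale * field


def generate_patient(template: SiteTemplate, spec: CohortSpec, index: int,
                     out_dir) -> dict:
    """Generate one phantom patient's DICOM-RT set; returns its manifest row.

    Writes ``<id>_rtstruct.dcm``, ``<id>_rtdose_treatment.dcm`` and
    ``<id>_rtdose_imaging.dcm`` (per-fraction imaging dose at
    ``spec.mu_reference`` MU). Fully determined by (template, spec, index).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = _patient_rng(spec.seed, index)
    pid = f"{template.site}_{spec.seed}_{index:03d}"

    # demographics: stratum from the cohort mixture, age uniform within it
    stratum = rng.choice(3, p=np.asarray(spec.age_proportions))
    lo, hi = AGE_STRATA_BOUNDS[stratum]
    age = int(rng.integers(lo, hi + 1))
    sex = str(rng.choice(["F", "M"]))
    laterality = (
        str(rng.choice(["left", "right"])) if template.mirror_by_laterality else ""
    )

    origin, spacing = _grid_geometry(template)
    frame_ref = deterministic_uid("frame", template.site, spec.seed, index)

    specs, target_center = _effective_specs(template, laterality or None)
    # per-patient anatomical and output jitter
    jitter_scale = float(np.clip(rng.normal(1.0, spec.noise), 0.5, 1.5))
    center_offset = rng.normal(0.0, 2.0, size=3)
    target_center = tuple(np.asarray(target_center) + center_offset)
    imaging_scale = float(np.clip(rng.normal(1.0, spec.noise / 2), 0.5, 1.5))

    nz = template.grid_shape[0]
    z_centers = origin[2] + spacing[2] * np.arange(nz)
    rois = []
    for s in specs:
        contours = _contours_for(s, z_centers)
        rois.append(ROI(name=s.name, contours=contours))
    structure = StructureSet(rois=rois, frame_ref=frame_ref)

    treatment = DoseGrid(
        origin=origin,
        spacing=spacing,
        values=_treatment_field(template, origin, spacing, target_center, jitter_scale),
        frame_ref=frame_ref,
    )
    per_fraction_iso = spec.imaging_dose_per_mu * spec.mu_reference
    imaging = DoseGrid(
        origin=origin,
        spacing=spacing,
        values=_imaging_field(template, origin, spacing, per_fraction_iso, imaging_scale),
        frame_ref=frame_ref,
    )

    struct_path = out_dir / f"{pid}_rtstruct.dcm"
    treat_path = out_dir / f"{pid}_rtdose_treatment.dcm"
    imaging_path = out_dir / f"{pid}_rtdose_imaging.dcm"
    write_rtstruct(structure, struct_path, uid_entropy=("struct", pid))
    write_rtdose(treatment, treat_path, uid_entropy=("treat", pid))
    write_rtdose(imaging, imaging_path, uid_entropy=("imaging", pid))

    return {
        "id": pid,
        "age_years": age,
        "sex": sex,
        "site": template.site,
        "laterality": laterality,
        "n_fractions": template.site_fraction_default,
        "treatment_dose_path": treat_path.name,
        "imaging_dose_path": imaging_path.name,
        "structure_path": struct_path.name,
    }


MANIFEST_COLUMNS = [
    "id", "age_years", "sex", "site", "laterality", "n_fractions",
    "treatment_dose_path", "imaging_dose_path", "structure_path",
]


def generate_cohort(spec: CohortSpec, out_dir) -> Path:
    """Generate a full synthetic cohort; returns the manifest CSV path.

    The manifest matches the cohort pipeline's input schema; file paths are
    relative to the manifest's directory.
    """
    template = SITE_TEMPLATES[spec.site]
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = [generate_patient(template, spec, i, out_dir) for i in range(spec.n_patients)]
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=MANIFEST_COLUMNS, lineterminator="\n")
        writer.writeheader()
        writer.writerows(rows)
    return manifest


# ---------------------------------------------------------------------------
# Analytic DVH fixtures
# ---------------------------------------------------------------------------

def _brute_force_metrics(midpoints, fractions, alpha_prime=0.085, geud_n=0.25):
    """Independent scalar evaluation by direct python-level summation."""
    mean = sum(float(v) * float(d) for v, d in zip(fractions, midpoints))
    oed_val = sum(
        float(v) * float(d) * float(np.exp(-alpha_prime * d))
        for v, d in zip(fractions, midpoints)
    )
    geud_val = (
        sum(float(v) * float(d) ** (1.0 / geud_n) for v, d in zip(fractions, midpoints))
        ** geud_n
    )
    return {"mean": mean, "oed": oed_val, "geud": geud_val,
            "alpha_prime": alpha_prime, "geud_n": geud_n}


def make_reference_dvh_fixtures() -> dict:
    """Canonical analytic DVH fixtures with independently computed metrics.

    Returns ``{name: (DifferentialDVH, expected)}`` where ``expected`` holds
    mean dose, OED(alpha'=0.085) and gEUD(n=0.25) from a direct brute-force
    evaluator. Covers a uniform 2 Gy organ, an equal-volume two-level
    {1, 3} Gy organ, a 0-10 Gy linear ramp (at two bin widths), and an
    unirradiated organ.
    """
    fixtures = {}

    edges = np.array([1.9, 2.1])
    dvh = DifferentialDVH(edges, np.array([1.0]), roi_name="uniform_2gy")
    fixtures["uniform_2gy"] = (dvh, _brute_force_metrics(dvh.bin_midpoints, dvh.volume_fraction))

    edges = np.array([0.5, 1.5, 2.5, 3.5])
    dvh = DifferentialDVH(edges, np.array([0.5, 0.0, 0.5]), roi_name="two_level_1_3gy")
    fixtures["two_level_1_3gy"] = (dvh, _brute_force_metrics(dvh.bin_midpoints, dvh.volume_fraction))

    for label, bw in (("ramp_0_10gy_coarse", 0.1), ("ramp_0_10gy_fine", 0.001)):
        doses = np.linspace(0.0, 10.0, 10001)
        n_bins = int(np.floor(doses.max() / bw)) + 1
        edges = bw * np.arange(n_bins + 1)
        counts, _ = np.histogram(doses, bins=edges)
        dvh = DifferentialDVH(edges, counts / doses.size, roi_name=label)
        fixtures[label] = (dvh, _brute_force_metrics(dvh.bin_midpoints, dvh.volume_fraction))

    edges = np.array([-0.005, 0.005])  # symmetric zero bin: midpoint exactly 0
    dvh = DifferentialDVH(edges, np.array([1.0]), roi_name="all_zero")
    fixtures["all_zero"] = (dvh, _brute_force_metrics(dvh.bin_midpoints, dvh.volume_fraction))
    return fixtures
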