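"""Synthetic allele-expression data with known ground truth.

Three generators live here, one per downstream stage:

* :func:`simulate_population` — per-cell paired allele intensities under a
  per-copy stochastic silencing model, reproducing the observed continuum
  from fully biallelic to monoallelic expression;
* :func:`render_image_stack` — two-channel confocal-like z-stacks in which
  each cell is a spherical nucleus whose interior intensity encodes its
  allele values, for exercising the image-cytometry stage;
* :func:`generate_annotation_fixture` — GFF3 gene models, monoallelic-call
  tables and gene→term maps with planted intronless/MAE structure, for
  exercising the enrichment stage.

Every generator is fully determined by its parameters and seed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from ._exceptions import GeometryError, ParameterError
from .params import SimulationParams
from .stack import ImageStack

DATASET_COLUMNS = ["cell_id", "experiment_id", "group_label", "tissue", "x", "y"]


def expected_intrinsic_noise(ploidy_N: int, silencing_q: float) -> float:
    """Mean per-cell intrinsic noise under pure per-copy silencing.

    With active copy counts a, b ~ Binomial(N, 1−q) per allele and no other
    noise source, normalized expression is a/(N(1−q)) per allele, so
    E[(x−y)²]/2 = N·q(1−q)/(N(1−q))² / ... = q / (N(1−q)).
    """
    if ploidy_N < 1:
        raise ParameterError("ploidy_N must be >= 1")
    if not (0.0 <= silencing_q < 1.0):
        raise ParameterError(
            "silencing_q must lie in [0, 1); the mean noise is undefined at q=1"
        )
    return silencing_q / (ploidy_N * (1.0 - silencing_q))


def simulate_population(params: SimulationParams) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate paired allele intensities for a population of cells.

    Per cell: shared extrinsic factor E ~ lognormal(0, sigma_extrinsic)
    (unit median), active copy counts a, b ~ Binomial(N, 1−q) drawn
    independently per allele, per-allele intrinsic factors I_x, I_y
    ~ lognormal(0, sigma_intrinsic), then

        x = gain_red[exp] · E · I_x · base_expression · (a/N) + ε_x

    (y analogous with gain_green and b), ε additive Gaussian detector noise,
    negative values clipped to 0.

    Returns
    -------
    cells, truth : DataFrame
        ``cells`` has columns ``cell_id, experiment_id, group_label, tissue,
        x, y``; ``truth`` records the active copy counts a, b and active
        fractions per cell.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n_exp = params.n_experiments
    cpe = params.cells_per_experiment
    n = n_exp * cpe
    N = params.ploidy_N
    q = params.silencing_q

    # draw order is part of the reproducibility contract
    E = rng.lognormal(0.0, params.sigma_extrinsic, n) if params.sigma_extrinsic > 0 else np.ones(n)
    a = rng.binomial(N, 1.0 - q, n)
    b = rng.binomial(N, 1.0 - q, n)
    Ix = rng.lognormal(0.0, params.sigma_intrinsic, n) if params.sigma_intrinsic > 0 else np.ones(n)
    Iy = rng.lognormal(0.0, params.sigma_intrinsic, n) if params.sigma_intrinsic > 0 else np.ones(n)
    eps_x = rng.normal(0.0, params.measurement_sd, n) if params.measurement_sd > 0 else np.zeros(n)
    eps_y = rng.normal(0.0, params.measurement_sd, n) if params.measurement_sd > 0 else np.zeros(n)

    exp_idx = np.repeat(np.arange(n_exp), cpe)
    gr = params.gains("gain_red")[exp_idx]
    gg = params.gains("gain_green")[exp_idx]
    base = params.base_expression

    x = np.clip(gr * E * Ix * base * (a / N) + eps_x, 0.0, None)
    y = np.clip(gg * E * Iy * base * (b / N) + eps_y, 0.0, None)

    cell_ids = [f"c{i + 1:04d}" for i in np.tile(np.arange(cpe), n_exp)]
    exp_ids = [f"exp{i + 1}" for i in exp_idx]
    cells = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "experiment_id": exp_ids,
            "group_label": params.group_label,
            "tissue": params.tissue,
            "x": x,
            "y": y,
        }
    )
    truth = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "experiment_id": exp_ids,
            "active_copies_red": a,
            "active_copies_green": b,
            "active_fraction_red": a / N,
            "active_fraction_green": b / N,
        }
    )
    return cells, truth


# ---------------------------------------------------------------------------
# image rendering


@dataclass
class NucleusGeometry:
    """Scene geometry for rendered stacks.

    Nuclei are spheres of ``radius`` voxels placed on a regular 3-D grid
    with at least ``margin`` empty voxels between bounding boxes, on a
    constant ``background``.  ``shape`` (z, y, x) is computed to fit the
    requested cells when omitted.
    """

    radius: int = 4
    margin: int = 3
    background: float = 5.0
    rendering_noise_sd: float = 1.0
    shape: Optional[tuple[int, int, int]] = None
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ParameterError("radius must be >= 1")
        if self.margin < 0:
            raise ParameterError("margin must be >= 0")
        if self.background < 0:
            raise ParameterError("background must be >= 0")
        if self.rendering_noise_sd < 0:
            raise ParameterError("rendering_noise_sd must be >= 0")
        if self.bit_depth not in (8, 16):
            raise ParameterError("bit_depth must be 8 or 16")


def render_image_stack(
    cells: pd.DataFrame,
    geometry: NucleusGeometry | None = None,
    seed: int = 0,
) -> tuple[ImageStack, pd.DataFrame]:
    """Render cells as spherical nuclei in a two-channel z-stack.

    Each cell's nucleus interior is set to its ``x`` value in the red
    channel and ``y`` in the green channel, plus Gaussian rendering noise;
    everything else is constant background.  Returns the stack and a
    ground-truth ROI table (cell_id, centroid z/y/x, radius, true values).
    """
    geometry = geometry or NucleusGeometry()
    n = len(cells)
    if n == 0:
        raise ParameterError("cells must contain at least one row")
    pitch = 2 * geometry.radius + 1 + geometry.margin

    if geometry.shape is None:
        # smallest near-cubic grid that fits n nuclei
        per_side = int(np.ceil(n ** (1.0 / 3.0)))
        nz = int(np.ceil(n / per_side**2))
        dims = [nz, per_side, per_side]
        shape = tuple(d * pitch + geometry.margin for d in dims)
    else:
        shape = geometry.shape
        dims = [max((s - geometry.margin) // pitch, 0) for s in shape]
        if dims[0] * dims[1] * dims[2] < n:
            raise GeometryError(
                f"cannot place {n} non-overlapping nuclei of radius "
                f"{geometry.radius} in shape {shape}"
            )

    rng = np.random.default_rng(seed)
    max_val = 2**geometry.bit_depth - 1
    vol = np.full((shape[0], 2, shape[1], shape[2]), geometry.background, dtype=np.float64)

    zz, yy, xx = np.mgrid[: shape[0], : shape[1], : shape[2]]
    rois = []
    for i, row in enumerate(cells.itertuples(index=False)):
        gz = i // (dims[1] * dims[2])
        gy = (i // dims[2]) % dims[1]
        gx = i % dims[2]
        cz = geometry.margin + geometry.radius + gz * pitch
        cy = geometry.margin + geometry.radius + gy * pitch
        cx = geometry.margin + geometry.radius + gx * pitch
        mask = (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2 <= geometry.radius**2
        vol[:, 0][mask] = row.x
        vol[:, 1][mask] = row.y
        rois.append(
            {
                "cell_id": row.cell_id,
                "z": cz,
                "y": cy,
                "x": cx,
                "radius": geometry.radius,
                "true_red": row.x,
                "true_green": row.y,
            }
        )

    if geometry.rendering_noise_sd > 0:
        vol += rng.normal(0.0, geometry.rendering_noise_sd, vol.shape)
    vol = np.clip(np.rint(vol), 0, max_val)
    dtype = np.uint8 if geometry.bit_depth == 8 else np.uint16
    stack = ImageStack(vol.astype(dtype), bit_depth=geometry.bit_depth)
    return stack, pd.DataFrame(rois)


# ---------------------------------------------------------------------------
# annotation fixtures


@dataclass
class AnnotationFixture:
    """Synthetic annotation bundle with planted ground truth."""

    gff3: str
    mae_table: pd.DataFrame  # gene_id, mae_call
    term_map: pd.DataFrame  # gene_id, term_id
    intronless_ids: frozenset
    enriched_term: str


def generate_annotation_fixture(
    n_genes: int,
    frac_intronless: float = 0.06,
    frac_mae_intronless: float = 0.64,
    frac_mae_intronful: float = 0.20,
    seed: int = 0,
    n_null_terms: int = 20,
    enriched_term_rate_in: float = 0.40,
    enriched_term_rate_bg: float = 0.02,
    null_term_rate: float = 0.05,
) -> AnnotationFixture:
    """Generate a GFF3 annotation, MAE-call table and gene→term map.

    The number of intronless genes is the nearest integer to
    ``n_genes * frac_intronless`` (Python's round).  Intronless genes carry
    only single-exon transcripts; intron-bearing genes carry at least one
    multi-exon transcript (occasionally plus a single-exon isoform, so the
    strict classification rule is exercised).  MAE calls are Bernoulli at
    the two stated rates; one enriched term is planted on the intronless
    set at ``enriched_term_rate_in`` vs ``enriched_term_rate_bg`` elsewhere.
    """
    if n_genes < 1:
        raise ParameterError("n_genes must be >= 1")
    for name, v in (
        ("frac_intronless", frac_intronless),
        ("frac_mae_intronless", frac_mae_intronless),
        ("frac_mae_intronful", frac_mae_intronful),
    ):
        if not (0.0 <= v <= 1.0):
            raise ParameterError(f"{name} must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    n_intronless = int(round(n_genes * frac_intronless))
    gene_ids = [f"g{i + 1:05d}" for i in range(n_genes)]
    intronless = frozenset(
        rng.choice(gene_ids, size=n_intronless, replace=False).tolist()
    )

    buf = io.StringIO()
    buf.write("##gff-version 3\n")
    pos = 1
    for gid in gene_ids:
        strand = "+" if rng.random() < 0.5 else "-"
        single = gid in intronless
        transcripts = []
        if single:
            exon_len = int(rng.integers(200, 900))
            transcripts.append([(pos, pos + exon_len - 1)])
        else:
            n_exons = int(rng.integers(2, 5))
            exons, p = [], pos
            for _ in range(n_exons):
                el = int(rng.integers(100, 300))
                exons.append((p, p + el - 1))
                p += el + int(rng.integers(50, 200))
            transcripts.append(exons)
            if rng.random() < 0.2:  # single-exon isoform; gene stays intronful
                transcripts.append([exons[0]])
        gstart = min(e[0] for t in transcripts for e in t)
        gend = max(e[1] for t in transcripts for e in t)
        buf.write(
            f"chrI\tallelenoise\tgene\t{gstart}\t{gend}\t.\t{strand}\t.\tID={gid}\n"
        )
        for ti, exons in enumerate(transcripts, 1):
            tid = f"{gid}.t{ti}"
            buf.write(
                f"chrI\tallelenoise\tmRNA\t{exons[0][0]}\t{exons[-1][1]}\t.\t"
                f"{strand}\t.\tID={tid};Parent={gid}\n"
            )
            for s, e in exons:
                buf.write(
                    f"chrI\tallelenoise\texon\t{s}\t{e}\t.\t{strand}\t.\tParent={tid}\n"
                )
        pos = gend + int(rng.integers(500, 2000))

    is_intronless = np.array([g in intronless for g in gene_ids])
    rate = np.where(is_intronless, frac_mae_intronless, frac_mae_intronful)
    mae = np.where(rng.random(n_genes) < rate, "monoallelic", "biallelic")
    mae_table = pd.DataFrame({"gene_id": gene_ids, "mae_call": mae})

    rows = []
    enriched_term = "T_ENRICHED"
    enr_rate = np.where(is_intronless, enriched_term_rate_in, enriched_term_rate_bg)
    hit = rng.random(n_genes) < enr_rate
    for g, h in zip(gene_ids, hit):
        if h:
            rows.append({"gene_id": g, "term_id": enriched_term})
    for t in range(n_null_terms):
        hit = rng.random(n_genes) < null_term_rate
        for g, h in zip(gene_ids, hit):
            if h:
                rows.append({"gene_id": g, "term_id": f"T{t + 1:03d}"})
    term_map = pd.DataFrame(rows, columns=["gene_id", "term_id"])

    return AnnotationFixture(
        gff3=buf.getvalue(),
        mae_table=mae_table,
        term_map=term_map,
        intronless_ids=intronless,
        enriched_term=enriched_term,
    )
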