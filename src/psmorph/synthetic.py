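"""Synthetic data with known ground truth for every pipeline stage.

This module fabricates the four kinds of input the analysis consumes:

* two-channel paraspeckle scenes as localization tables (core–shell
  particles with ring-shaped 5'/3' shell labels, optional rod or aggregate
  clusters, a speckle channel with shell enrichment, and uniform
  nucleoplasmic background),
* exponential RNA decay time courses with an optional initial plateau and
  multiplicative lognormal noise,
* SAM alignment records with and without non-templated 3' A-tails,
* local-splicing-variation (LSV) tables with junction-level deltaPSI values,
  change probabilities, and a known regulated subset.

No attempt is made to model emitter photophysics or camera frames; the
scenes start at the localization-table level that real single-molecule
pipelines reach after spot fitting.  All distributional choices are
stand-ins chosen for plausibility, not fits to real data.  Every generator
takes an explicit seed (or ``numpy.random.Generator``) and is fully
deterministic given it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

LOC_COLUMNS = ["x_nm", "y_nm", "frame", "photons", "ellipticity", "psf_width_px"]

#: FWHM of a Gaussian = FWHM_FACTOR * sigma
FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Paraspeckle scenes
# ---------------------------------------------------------------------------

@dataclass
class ChannelModel:
    """Label geometry of one imaging channel.

    kind
        ``"shell_ring"`` — points on an annulus at the particle's shell
        radius (the 5' or 3' end label of the scaffold RNA);
        ``"core_disk"`` — points uniform in the particle core (middle-region
        label); ``"speckle"`` — diffuse nucleoplasmic signal plus bright
        speckle blobs and, for a fraction of particles, a shell-enrichment
        annulus (the SR-protein channel).
    points_per_particle
        Localizations drawn per particle for particle-bound kinds.
    core_fraction
        For ``shell_ring``: fraction of the particle signal placed in the
        core instead of the shell (mis-packaged 5' ends sit inside).
    shell_mode
        ``"ring"`` samples the shell as a 2-D annulus (a thin optical
        section through the particle equator, as in scanning
        super-resolution data); ``"sphere"`` samples points on the full
        3-D shell surface and projects them, giving the filled, rim-bright
        disks seen in widefield localization data.
    """

    name: str
    kind: str = "shell_ring"
    points_per_particle: int = 300
    core_fraction: float = 0.0
    shell_mode: str = "ring"
    # speckle-kind extras
    n_speckles: int = 0
    speckle_sigma_nm: float = 150.0
    points_per_speckle: int = 400
    decorated_fraction: float = 0.0
    shell_ring_range_nm: tuple[float, float] = (100.0, 180.0)
    points_per_decoration: int = 120

    def __post_init__(self) -> None:
        if self.kind not in ("shell_ring", "core_disk", "speckle"):
            raise ValueError(f"unknown channel kind {self.kind!r}")
        if self.points_per_particle < 0:
            raise ValueError("points_per_particle must be >= 0")
        if not 0.0 <= self.core_fraction <= 1.0:
            raise ValueError("core_fraction must be in [0, 1]")
        if self.shell_mode not in ("ring", "sphere"):
            raise ValueError(f"unknown shell_mode {self.shell_mode!r}")


@dataclass
class ClusterSpec:
    """Grouping of particles into higher-order clusters.

    ``"none"`` leaves particles isolated; ``"rod"`` places k sphere centers
    on a line at a spacing of one diameter (elongated cylinder-like
    clusters); ``"aggregate"`` packs k spheres by hard-sphere random
    attachment (irregular grape-like clusters).
    """

    kind: str = "none"
    k: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("none", "rod", "aggregate"):
            raise ValueError(f"unknown cluster kind {self.kind!r}")
        if self.kind != "none" and self.k < 2:
            raise ValueError("cluster size k must be >= 2")


@dataclass
class SceneParams:
    """Parameters of one simulated two-channel scene.

    Lengths are nanometres.  The default shell radius of 180 nm encodes the
    canonical fixed ~360 nm particle diameter; the shell thickness is the
    FWHM of the radial label distribution around that radius.
    """

    field_size_nm: tuple[float, float] = (6000.0, 6000.0)
    pixel_size_nm: float = 10.0
    n_particles: int = 10
    shell_radius_mean_nm: float = 180.0
    shell_radius_sd_nm: float = 0.0
    shell_thickness_nm: float = 60.0
    cluster: ClusterSpec = field(default_factory=ClusterSpec)
    channels: tuple[ChannelModel, ...] = (
        ChannelModel("fiveprime", "shell_ring"),
        ChannelModel("threeprime", "shell_ring"),
    )
    background_per_um2: float = 2.0
    loc_noise_sd_nm: float = 5.0
    min_separation_nm: float = 900.0
    n_frames: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.field_size_nm) <= 0 or self.pixel_size_nm <= 0:
            raise ValueError("field and pixel sizes must be positive")
        if self.n_particles < 0:
            raise ValueError("n_particles must be >= 0")
        if self.shell_radius_mean_nm <= 0 or self.shell_thickness_nm <= 0:
            raise ValueError("shell geometry must be positive")
        if self.shell_radius_sd_nm < 0 or self.loc_noise_sd_nm < 0:
            raise ValueError("noise scales must be >= 0")


@dataclass
class GroundTruth:
    """Per-particle truth for a simulated scene."""

    particles: pd.DataFrame  # columns: particle_id, cx_nm, cy_nm, radius_nm, cluster_id
    decorated_ids: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_particles(self) -> int:
        return len(self.particles)


def _place_centers(params: SceneParams, rng: np.random.Generator):
    """Sample particle centers and cluster membership.

    Isolated particles are rejection-sampled with a minimum pairwise
    separation; clusters place a group anchor the same way and then grow the
    group geometrically (rod: collinear at one diameter spacing; aggregate:
    hard-sphere random attachment).
    """
    h, w = params.field_size_nm
    r_mean = params.shell_radius_mean_nm
    margin = 2.0 * r_mean + 2.0 * params.shell_thickness_nm
    if w <= 2 * margin or h <= 2 * margin:
        raise ValueError("field too small for particle radius")

    def radius() -> float:
        r = rng.normal(r_mean, params.shell_radius_sd_nm) if params.shell_radius_sd_nm > 0 else r_mean
        return max(r, 0.2 * r_mean)

    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    cluster_ids: list[int] = []

    k = params.cluster.k if params.cluster.kind != "none" else 1
    n_groups = params.n_particles // k
    leftover = params.n_particles - n_groups * k

    def far_enough(x, y, min_d):
        return all((x - cx) ** 2 + (y - cy) ** 2 >= min_d ** 2 for cx, cy in centers)

    group_sep = params.min_separation_nm + (k - 1) * 2.0 * r_mean
    for g in range(n_groups + (1 if leftover else 0)):
        size = k if g < n_groups else leftover
        for _ in range(10000):
            ax = rng.uniform(margin, w - margin)
            ay = rng.uniform(margin, h - margin)
            if far_enough(ax, ay, group_sep):
                break
        else:
            raise RuntimeError("could not place particles; field too crowded")
        if params.cluster.kind == "rod" and size > 1:
            theta = rng.uniform(0, 2 * np.pi)
            rads = [radius() for _ in range(size)]
            step = 2.0 * float(np.mean(rads))
            for i in range(size):
                centers.append((ax + i * step * math.cos(theta),
                                ay + i * step * math.sin(theta)))
                radii.append(rads[i])
                cluster_ids.append(g)
        elif params.cluster.kind == "aggregate" and size > 1:
            members = [(ax, ay)]
            mrad = [radius()]
            while len(members) < size:
                base = members[rng.integers(len(members))]
                r_new = radius()
                for _ in range(200):
                    th = rng.uniform(0, 2 * np.pi)
                    d = mrad[0] + r_new  # touch distance (hard spheres)
                    x = base[0] + d * math.cos(th)
                    y = base[1] + d * math.sin(th)
                    if all((x - mx) ** 2 + (y - my) ** 2 >= (0.99 * d) ** 2
                           for mx, my in members):
                        members.append((x, y))
                        mrad.append(r_new)
                        break
                else:  # pragma: no cover - pathological packing
                    break
            for i, (x, y) in enumerate(members):
                centers.append((x, y))
                radii.append(mrad[i])
                cluster_ids.append(g)
        else:
            for _ in range(size):
                centers.append((ax, ay))
                radii.append(radius())
                cluster_ids.append(g)

    return np.array(centers).reshape(-1, 2), np.array(radii), np.array(cluster_ids)


def _finish_table(xy: np.ndarray, params: SceneParams,
                  rng: np.random.Generator) -> pd.DataFrame:
    """Attach frame/photon/PSF-quality columns and clip to the field."""
    h, w = params.field_size_nm
    n = len(xy)
    df = pd.DataFrame({
        "x_nm": xy[:, 0], "y_nm": xy[:, 1],
        "frame": rng.integers(0, params.n_frames, size=n),
        "photons": rng.gamma(2.0, 800.0, size=n),
        "ellipticity": rng.beta(1.2, 10.0, size=n),
        "psf_width_px": rng.normal(0.95, 0.08, size=n),
    })
    df = df[(df.x_nm >= 0) & (df.x_nm < w) & (df.y_nm >= 0) & (df.y_nm < h)]
    df = df.sort_values(["frame", "x_nm"], kind="stable").reset_index(drop=True)
    return df[LOC_COLUMNS]


def _ring_points(center, n, ring_radius, thickness_fwhm, noise_sd, rng):
    theta = rng.uniform(0, 2 * np.pi, size=n)
    r = rng.normal(ring_radius, thickness_fwhm / FWHM_FACTOR, size=n)
    xy = np.column_stack([center[0] + r * np.cos(theta),
                          center[1] + r * np.sin(theta)])
    if noise_sd > 0:
        xy += rng.normal(0.0, noise_sd, size=xy.shape)
    return xy


def _sphere_proj_points(center, n, shell_radius, thickness_fwhm, noise_sd, rng):
    """Project uniform points on a 3-D shell of the given radius to 2-D."""
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = rng.normal(shell_radius, thickness_fwhm / FWHM_FACTOR, size=n)
    xy = np.column_stack([center[0] + r * v[:, 0], center[1] + r * v[:, 1]])
    if noise_sd > 0:
        xy += rng.normal(0.0, noise_sd, size=xy.shape)
    return xy


def _disk_points(center, n, disk_radius, noise_sd, rng):
    theta = rng.uniform(0, 2 * np.pi, size=n)
    r = disk_radius * np.sqrt(rng.uniform(0, 1, size=n))
    xy = np.column_stack([center[0] + r * np.cos(theta),
                          center[1] + r * np.sin(theta)])
    if noise_sd > 0:
        xy += rng.normal(0.0, noise_sd, size=xy.shape)
    return xy


def simulate_scene(params: SceneParams) -> tuple[dict[str, pd.DataFrame], GroundTruth]:
    """Simulate one multi-channel localization scene.

    Returns a mapping from channel name to a localization table (columns
    ``x_nm, y_nm, frame, photons, ellipticity, psf_width_px``) and the
    ground truth.  Determinism: two calls with equal params (including
    ``seed``) produce identical tables.
    """
    rng = _rng(params.seed)
    if params.n_particles > 0:
        centers, radii, cluster_ids = _place_centers(params, rng)
    else:
        centers = np.empty((0, 2))
        radii = np.empty(0)
        cluster_ids = np.empty(0, dtype=int)

    truth = GroundTruth(pd.DataFrame({
        "particle_id": np.arange(len(centers)),
        "cx_nm": centers[:, 0] if len(centers) else np.empty(0),
        "cy_nm": centers[:, 1] if len(centers) else np.empty(0),
        "radius_nm": radii,
        "cluster_id": cluster_ids,
    }))

    h, w = params.field_size_nm
    area_um2 = (h / 1000.0) * (w / 1000.0)
    tables: dict[str, pd.DataFrame] = {}
    for ch in params.channels:
        pieces = []
        if ch.kind in ("shell_ring", "core_disk"):
            for (cx, cy), r in zip(centers, radii):
                n = ch.points_per_particle
                if ch.kind == "core_disk":
                    pieces.append(_disk_points((cx, cy), n, 0.6 * r,
                                               params.loc_noise_sd_nm, rng))
                else:
                    n_core = rng.binomial(n, ch.core_fraction) if ch.core_fraction else 0
                    if n - n_core:
                        sampler = (_ring_points if ch.shell_mode == "ring"
                                   else _sphere_proj_points)
                        pieces.append(sampler((cx, cy), n - n_core, r,
                                              params.shell_thickness_nm,
                                              params.loc_noise_sd_nm, rng))
                    if n_core:
                        pieces.append(_disk_points((cx, cy), n_core, 0.6 * r,
                                                   params.loc_noise_sd_nm, rng))
        elif ch.kind == "speckle":
            for _ in range(ch.n_speckles):
                sc = (rng.uniform(0, w), rng.uniform(0, h))
                pieces.append(rng.normal(sc, ch.speckle_sigma_nm,
                                         size=(ch.points_per_speckle, 2)))
            if ch.decorated_fraction > 0 and len(centers):
                n_dec = int(round(ch.decorated_fraction * len(centers)))
                dec = rng.choice(len(centers), size=n_dec, replace=False)
                truth.decorated_ids[ch.name] = np.sort(dec)
                lo, hi = ch.shell_ring_range_nm
                for i in dec:
                    theta = rng.uniform(0, 2 * np.pi, ch.points_per_decoration)
                    r = rng.uniform(lo, hi, ch.points_per_decoration)
                    pieces.append(np.column_stack([
                        centers[i, 0] + r * np.cos(theta),
                        centers[i, 1] + r * np.sin(theta),
                    ]) + rng.normal(0, params.loc_noise_sd_nm,
                                    (ch.points_per_decoration, 2)))
        n_bg = rng.poisson(params.background_per_um2 * area_um2)
        if n_bg:
            pieces.append(np.column_stack([rng.uniform(0, w, n_bg),
                                           rng.uniform(0, h, n_bg)]))
        xy = np.vstack(pieces) if pieces else np.empty((0, 2))
        tables[ch.name] = _finish_table(xy, params, rng)
    return tables, truth


def write_localizations(table: pd.DataFrame, path: str | Path) -> None:
    """Write a localization table in the package CSV dialect."""
    table.to_csv(path, index=False)


def read_localizations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(LOC_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"localization CSV missing columns: {sorted(missing)}")
    return df[LOC_COLUMNS]


# ---------------------------------------------------------------------------
# Decay series
# ---------------------------------------------------------------------------

def decay_model(t: np.ndarray, n0: float, half_life: float,
                plateau: float = 0.0) -> np.ndarray:
    """Noise-free plateau-then-exponential abundance at times ``t`` (min)."""
    t = np.asarray(t, dtype=float)
    k = math.log(2.0) / half_life
    return np.where(t <= plateau, n0, n0 * np.exp(-k * (t - plateau)))


def simulate_decay_series(n0: float, half_life: float, plateau: float,
                          timepoints: Sequence[float], noise_cv: float,
                          seed, n_replicates: int = 1) -> pd.DataFrame:
    """Simulate a decay time course.

    The abundance stays at ``n0`` until ``plateau`` minutes, then decays
    exponentially with the given half-life.  Each observation is multiplied
    by lognormal noise with unit mean and coefficient of variation
    ``noise_cv``.  Returns columns ``time_min, value, replicate``.
    """
    if half_life <= 0:
        raise ValueError("half_life must be positive")
    if plateau < 0:
        raise ValueError("plateau must be >= 0")
    t = np.asarray(timepoints, dtype=float)
    if np.any(t < 0):
        raise ValueError("timepoints must be >= 0")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = _rng(seed)
    clean = decay_model(t, n0, half_life, plateau)
    rows = []
    for rep in range(n_replicates):
        if noise_cv > 0:
            sigma = math.sqrt(math.log(1.0 + noise_cv ** 2))
            noise = rng.lognormal(-0.5 * sigma ** 2, sigma, size=len(t))
        else:
            noise = np.ones(len(t))
        rows.append(pd.DataFrame({"time_min": t, "value": clean * noise,
                                  "replicate": rep}))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Reads with / without non-templated A-tails
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def simulate_reads(region: tuple[str, int, int], n_pa: int, n_plain: int,
                   tail_len: int = 10, read_len: int = 50,
                   frac_reverse: float = 0.5, seed=0,
                   ref_length: int | None = None,
                   ) -> tuple[pysam.AlignmentHeader, list[pysam.AlignedSegment]]:
    """Construct SAM records whose aligned 3' ends fall inside ``region``.

    ``n_pa`` reads carry a soft-clipped non-templated A-run of ``tail_len``
    at their 3' end (appearing as a trailing A-clip on forward reads and a
    leading T-clip on reverse reads); ``n_plain`` reads align end to end.
    ``region`` is (chrom, start, end), 0-based half-open.
    """
    if n_pa < 0 or n_plain < 0:
        raise ValueError("read counts must be >= 0")
    if n_pa > 0 and tail_len <= 0:
        raise ValueError("tail_len must be positive when n_pa > 0")
    chrom, start, end = region
    if end <= start or start < 0:
        raise ValueError("invalid region")
    rng = _rng(seed)
    if ref_length is None:
        ref_length = end + read_len + 1000
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": chrom, "LN": int(ref_length)}],
    })

    records = []
    aln_len = read_len - tail_len

    def base_record(name, pos, cigar, seq, reverse):
        a = pysam.AlignedSegment(header)
        a.query_name = name
        a.query_sequence = seq
        a.reference_id = 0
        a.reference_start = int(pos)
        a.cigarstring = cigar
        a.mapping_quality = 60
        a.is_reverse = bool(reverse)
        a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
        return a

    for i in range(n_pa):
        reverse = rng.random() < frac_reverse
        if reverse:
            # 3' end of a reverse read is its leftmost reference position;
            # the A-tail reverse-complements to a leading soft-clipped T-run.
            pos = int(rng.integers(start, end))
            seq = "T" * tail_len + _random_seq(rng, aln_len)
            cigar = f"{tail_len}S{aln_len}M"
        else:
            end3 = int(rng.integers(start + 1, end + 1))
            pos = max(end3 - aln_len, 0)
            seq = _random_seq(rng, aln_len) + "A" * tail_len
            cigar = f"{aln_len}M{tail_len}S"
        records.append(base_record(f"pa_{i}", pos, cigar, seq, reverse))

    for i in range(n_plain):
        reverse = rng.random() < frac_reverse
        if reverse:
            pos = int(rng.integers(start, end))
        else:
            end3 = int(rng.integers(start + 1, end + 1))
            pos = max(end3 - read_len, 0)
        records.append(base_record(f"plain_{i}", pos, f"{read_len}M",
                                   _random_seq(rng, read_len), reverse))
    return header, records


def write_sam(header: pysam.AlignmentHeader,
              records: Sequence[pysam.AlignedSegment], path: str | Path) -> None:
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for rec in records:
            fh.write(rec)


def read_sam(path: str | Path) -> list[pysam.AlignedSegment]:
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        return list(fh)


# ---------------------------------------------------------------------------
# LSV tables
# ---------------------------------------------------------------------------

EVENT_KINDS = ("cassette", "alt_3ss", "alt_5ss", "intron_retention")


def make_event_lsvs(kind: str, gene_id: str, lsv_prefix: str, base: int,
                    dpsi: float, probability: float) -> list[dict]:
    """Build the source/target LSV rows of one binary splicing event.

    Junction coordinates are 0-based half-open intron intervals
    (donor-side exon end, acceptor-side exon start).  ``dpsi`` (percent)
    is the change of the inclusion junction; closure puts ``-dpsi`` on the
    skipping/competing junction.
    """
    if kind not in EVENT_KINDS:
        raise ValueError(f"unknown event kind {kind!r}")
    d1, a_c = base + 200, base + 500        # exon1 donor, cassette acceptor
    d_c, a3 = base + 600, base + 1000       # cassette donor, exon3 acceptor

    def row(suffix, orientation, juncs, kinds, dpsis):
        return {
            "gene_id": gene_id,
            "lsv_id": f"{lsv_prefix}:{suffix}",
            "orientation": orientation,
            "junctions": juncs,
            "junction_kinds": kinds,
            "delta_psi": dpsis,
            "probability": probability,
        }

    if kind == "cassette":
        skip = (d1, a3)
        return [
            row("s", "source", [(d1, a_c), skip], ["junction", "junction"],
                [dpsi, -dpsi]),
            row("t", "target", [(d_c, a3), skip], ["junction", "junction"],
                [dpsi, -dpsi]),
        ]
    if kind == "alt_3ss":
        j1, j2 = (d1, a_c), (d1, a_c + 50)
        return [
            row("s", "source", [j1, j2], ["junction", "junction"], [dpsi, -dpsi]),
            row("t", "target", [j1, j2], ["junction", "junction"], [dpsi, -dpsi]),
        ]
    if kind == "alt_5ss":
        j1, j2 = (d1, a_c), (d1 - 50, a_c)
        return [
            row("s", "source", [j1, j2], ["junction", "junction"], [dpsi, -dpsi]),
            row("t", "target", [j1, j2], ["junction", "junction"], [dpsi, -dpsi]),
        ]
    # intron retention: a spliced junction competing with the unspliced intron
    j, ir = (d1, a_c), (d1, a_c)
    return [
        row("s", "source", [j, ir], ["junction", "intron"], [dpsi, -dpsi]),
        row("t", "target", [j, ir], ["junction", "intron"], [dpsi, -dpsi]),
    ]


def simulate_lsv_table(n_regulated: int, n_nonregulated: int, n_ambiguous: int,
                       event_mix: dict[str, float] | None = None, seed=0,
                       ) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate an LSV table with truth labels.

    Regulated rows satisfy max |deltaPSI| > 5 percent with change
    probability > 0.5; non-regulated rows satisfy max |deltaPSI| < 2
    percent with probability exactly 0; ambiguous rows fall in neither
    class (either the 2–5 percent gap, or a large deltaPSI with weak
    probability).  ``event_mix`` sets the proportion of event geometries
    among regulated rows and must sum to 1.
    """
    for n in (n_regulated, n_nonregulated, n_ambiguous):
        if n < 0:
            raise ValueError("counts must be >= 0")
    if event_mix is None:
        event_mix = {"cassette": 0.4, "alt_3ss": 0.2, "alt_5ss": 0.2,
                     "intron_retention": 0.2}
    if abs(sum(event_mix.values()) - 1.0) > 1e-9:
        raise ValueError("event_mix must sum to 1")
    rng = _rng(seed)
    kinds = list(event_mix)
    probs = np.array([event_mix[k] for k in kinds])

    rows: list[dict] = []
    labels: list[str] = []

    def add(row, label):
        rows.append(row)
        labels.append(label)

    base = 10_000
    i = 0
    while sum(lab == "regulated" for lab in labels) < n_regulated:
        kind = kinds[rng.choice(len(kinds), p=probs)]
        dpsi = float(rng.uniform(6.0, 30.0)) * (1 if rng.random() < 0.5 else -1)
        prob = float(rng.uniform(0.55, 1.0))
        for row in make_event_lsvs(kind, f"gene_reg_{i}", f"reg_{i}", base,
                                   dpsi, prob):
            if sum(lab == "regulated" for lab in labels) >= n_regulated:
                break
            row["true_event"] = kind
            add(row, "regulated")
        base += 2000
        i += 1
    for i in range(n_nonregulated):
        dpsi = float(rng.uniform(0.0, 1.9))
        row = make_event_lsvs("cassette", f"gene_non_{i}", f"non_{i}", base,
                              dpsi, 0.0)[0]
        row["true_event"] = "none"
        add(row, "non_regulated")
        base += 2000
    for i in range(n_ambiguous):
        if rng.random() < 0.5:
            dpsi, prob = float(rng.uniform(2.1, 4.9)), float(rng.uniform(0.0, 1.0))
        else:
            dpsi, prob = float(rng.uniform(6.0, 30.0)), float(rng.uniform(0.0, 0.5))
        row = make_event_lsvs("cassette", f"gene_amb_{i}", f"amb_{i}", base,
                              dpsi, prob)[0]
        row["true_event"] = "none"
        add(row, "ambiguous")
        base += 2000

    columns = ["gene_id", "lsv_id", "orientation", "junctions",
               "junction_kinds", "delta_psi", "probability", "true_event"]
    df = pd.DataFrame(rows, columns=columns)
    return df, pd.Series(labels, name="truth", dtype=object)


def write_lsv_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write an LSV table as TSV (coordinates converted to 1-based closed)."""
    out = df.copy()
    out["junctions"] = out["junctions"].map(
        lambda js: ";".join(f"{s + 1}-{e}" for s, e in js))
    out["junction_kinds"] = out["junction_kinds"].map(";".join)
    out["delta_psi"] = out["delta_psi"].map(
        lambda ds: ";".join(f"{d:.4f}" for d in ds))
    out.to_csv(path, sep="\t", index=False)


def read_lsv_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV LSV table back to internal 0-based half-open coordinates."""
    df = pd.read_csv(path, sep="\t")
    df["junctions"] = df["junctions"].map(
        lambda s: [(int(a) - 1, int(b)) for a, b in
                   (j.split("-") for j in s.split(";"))])
    df["junction_kinds"] = df["junction_kinds"].map(lambda s: s.split(";"))
    df["delta_psi"] = df["delta_psi"].map(
        lambda s: [float(x) for x in s.split(";")])
    return df
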