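"""Synthetic inputs for every pipeline stage.

Three generators, all deterministic given their config seed:

* :func:`generate_toy_proteomes` — a source/target proteome pair with
  planted gene families: within a family, paralogs diverge more than the
  true cross-organism ortholog pair, so reciprocal best-match orthology can
  recover the planted mapping.
* :func:`render_field` — one two-channel fluorescence field with known
  nucleus and aggregate ground truth, the oracle for the quantifier.
* :func:`simulate_screen` — a plate-level screen with planted per-construct
  induction effects, SCR/GFP/CCT2 control wells, one round-1 pass and
  triplicate confirmation, under multiplicative lognormal noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import (
    ConfigError,
    FieldSimConfig,
    ProteomeSimConfig,
    ScreenSimConfig,
)

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: well roles used throughout the pipeline
ROLE_TEST, ROLE_SCR, ROLE_GFP, ROLE_CCT2 = "test", "SCR", "GFP", "CCT2"


# ---------------------------------------------------------------------------
# toy proteomes


def _mutate(seq: np.ndarray, divergence: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute exactly round(len*divergence) positions to a different residue."""
    n_mut = int(round(len(seq) * divergence))
    out = seq.copy()
    sites = rng.choice(len(seq), size=n_mut, replace=False)
    for i in sites:
        choices = AMINO_ACIDS[AMINO_ACIDS != out[i]]
        out[i] = rng.choice(choices)
    return out


def generate_toy_proteomes(
    config: ProteomeSimConfig,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]], pd.DataFrame]:
    """Generate a planted source/target proteome pair.

    Returns ``(source_records, target_records, truth)`` where records are
    ``(id, residue_string)`` pairs ready for FASTA writing and ``truth`` has
    columns ``source_id, true_target_id`` with ``true_target_id`` empty for
    genes planted without a target-organism counterpart.

    Family structure: each family has an ancestral sequence; every source
    paralog is the ancestor mutated by ``paralog_divergence / 2`` (so two
    paralogs differ by roughly ``paralog_divergence``), and each mapped
    source gene's true ortholog is that source sequence mutated by
    ``ortholog_divergence``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    source: list[tuple[str, str]] = []
    target: list[tuple[str, str]] = []
    rows = []
    n_source_total = 0
    planned: list[tuple[int, np.ndarray, int]] = []
    for fam in range(config.n_families):
        size = int(rng.integers(config.family_size_range[0], config.family_size_range[1] + 1))
        length = int(rng.integers(config.seq_length_range[0], config.seq_length_range[1] + 1))
        ancestor = rng.choice(AMINO_ACIDS, size=length)
        planned.append((fam, ancestor, size))
        n_source_total += size

    n_unmappable = int(round(config.frac_unmappable * n_source_total))
    unmappable = set(rng.choice(n_source_total, size=n_unmappable, replace=False).tolist())

    idx = 0
    for fam, ancestor, size in planned:
        for j in range(size):
            sid = f"src_f{fam:03d}_g{j}"
            src_seq = _mutate(ancestor, config.paralog_divergence / 2.0, rng)
            source.append((sid, "".join(src_seq)))
            if idx in unmappable:
                rows.append({"source_id": sid, "true_target_id": ""})
            else:
                tid = f"tgt_f{fam:03d}_g{j}"
                tgt_seq = _mutate(src_seq, config.ortholog_divergence, rng)
                target.append((tid, "".join(tgt_seq)))
                rows.append({"source_id": sid, "true_target_id": tid})
            idx += 1

    truth = pd.DataFrame(rows, columns=["source_id", "true_target_id"])
    return source, target, truth


# ---------------------------------------------------------------------------
# rendered fields


@dataclass
class RenderedField:
    """One simulated microscope field with ground truth."""

    nuclei_channel: np.ndarray
    gfp_channel: np.ndarray
    nucleus_centroids: list[tuple[float, float]] = field(default_factory=list)
    aggregate_centroids: list[tuple[float, float]] = field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return len(self.nucleus_centroids)

    @property
    def n_aggregates(self) -> int:
        return len(self.aggregate_centroids)


def _draw_disc(img: np.ndarray, center: tuple[float, float], radius: float,
               amplitude: float) -> None:
    """Add a soft-edged disc onto ``img`` in place (1 px antialias ramp)."""
    cy, cx = center
    r_ext = int(math.ceil(radius)) + 2
    y0, y1 = max(0, int(cy) - r_ext), min(img.shape[0], int(cy) + r_ext + 1)
    x0, x1 = max(0, int(cx) - r_ext), min(img.shape[1], int(cx) + r_ext + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d = np.hypot(yy - cy, xx - cx)
    img[y0:y1, x0:x1] += amplitude * np.clip(radius + 0.5 - d, 0.0, 1.0)


def render_field(config: FieldSimConfig) -> RenderedField:
    """Render one two-channel field from the config's stated world.

    Non-overlapping placement keeps nucleus centers at least one diameter
    apart and away from the borders; it raises :class:`ConfigError` when
    such placement is infeasible for ``n_cells`` in ``image_shape``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    h, w = config.image_shape
    r_mean, r_sd = config.nucleus_radius_px
    margin = r_mean * 2.5 + 2

    centers: list[tuple[float, float]] = []
    min_sep = 2.0 * (r_mean + 2 * r_sd) + 3.0
    # crude capacity check before rejection sampling
    if not config.allow_overlap and config.n_cells > 0:
        capacity = ((h - 2 * margin) * (w - 2 * margin)) / (min_sep ** 2)
        if capacity < config.n_cells:
            raise ConfigError(
                f"cannot place {config.n_cells} non-overlapping cells in a "
                f"{h}x{w} field; enlarge the image or allow overlap"
            )
    attempts = 0
    while len(centers) < config.n_cells:
        cand = (rng.uniform(margin, h - margin), rng.uniform(margin, w - margin))
        if config.allow_overlap or all(
            math.hypot(cand[0] - c[0], cand[1] - c[1]) >= min_sep for c in centers
        ):
            centers.append(cand)
        attempts += 1
        if attempts > 200 * max(config.n_cells, 1):
            raise ConfigError(
                "non-overlapping placement infeasible; too many cells for the field"
            )

    nuc = np.zeros((h, w), dtype=float)
    gfp = np.zeros((h, w), dtype=float)
    # radii truncated at +-2 sd: every rendered object stays resolvable
    # relative to the PSF, per the bright-visible-inclusion design
    radii = np.clip(rng.normal(r_mean, r_sd, size=len(centers)),
                    r_mean - 2 * r_sd, r_mean + 2 * r_sd)
    for c, r in zip(centers, radii):
        _draw_disc(nuc, c, r, config.nucleus_amplitude)
        # every cell expresses the diffuse reporter over a cytoplasm-sized disc
        _draw_disc(gfp, c, r * 2.2, config.diffuse_amplitude)

    n_agg = int(round(config.n_cells * config.aggregate_fraction))
    agg_centers: list[tuple[float, float]] = []
    if n_agg:
        which = rng.choice(len(centers), size=n_agg, replace=False)
        ar_mean, ar_sd = config.aggregate_radius_px
        # keep aggregates mutually separated so truth stays countable
        agg_sep = 2.0 * (ar_mean + 2 * ar_sd) + 2.0
        for i in which:
            cy, cx = centers[i]
            ac = None
            for _ in range(200):
                theta = rng.uniform(0, 2 * math.pi)
                rho = rng.uniform(radii[i] * 1.1, radii[i] * 1.8)
                cand = (cy + rho * math.sin(theta), cx + rho * math.cos(theta))
                if config.allow_overlap or all(
                    math.hypot(cand[0] - a[0], cand[1] - a[1]) >= agg_sep
                    for a in agg_centers
                ):
                    ac = cand
                    break
            if ac is None:  # crowded corner; accept the last draw
                ac = cand
            ar = float(np.clip(rng.normal(ar_mean, ar_sd),
                               max(1.2, ar_mean - 2 * ar_sd), ar_mean + 2 * ar_sd))
            _draw_disc(gfp, ac, ar,
                       config.aggregate_contrast * config.diffuse_amplitude)
            agg_centers.append(ac)

    if config.psf_sigma_px > 0:
        nuc = ndimage.gaussian_filter(nuc, config.psf_sigma_px)
        gfp = ndimage.gaussian_filter(gfp, config.psf_sigma_px)
    nuc += config.background_level + rng.normal(0, config.noise_sd, size=(h, w))
    gfp += config.background_level + rng.normal(0, config.noise_sd, size=(h, w))
    np.clip(nuc, 0, None, out=nuc)
    np.clip(gfp, 0, None, out=gfp)

    return RenderedField(nuc, gfp, centers, agg_centers)


# ---------------------------------------------------------------------------
# plate-level screens


@dataclass
class ScreenDataset:
    """Simulated screen: well table, construct truth, config echo.

    ``wells`` columns: experiment_id, round, well, gene, construct_id, role,
    true_effect, raw_pct. ``truth`` columns: gene, construct_id, status
    (suppressor|null), true_effect.
    """

    wells: pd.DataFrame
    truth: pd.DataFrame
    config: ScreenSimConfig


def _experiment_wells(
    exp_id: str,
    rnd: str,
    constructs: pd.DataFrame,
    config: ScreenSimConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """One experiment: every construct once plus the control wells."""
    rows = []
    widx = 0

    def well_name() -> str:
        nonlocal widx
        widx += 1
        return f"{exp_id}_w{widx:03d}"

    def noisy(effect: float) -> float:
        base = config.baseline_pct * effect
        if config.measurement_cv <= 0:
            return base
        sigma = math.sqrt(math.log(1.0 + config.measurement_cv ** 2))
        return float(base * rng.lognormal(-0.5 * sigma ** 2, sigma))

    for _ in range(config.n_scr_wells):
        rows.append((exp_id, rnd, well_name(), "", "", ROLE_SCR, 1.0, noisy(1.0)))
    rows.append((exp_id, rnd, well_name(), "GFP", "", ROLE_GFP,
                 config.gfp_effect, noisy(config.gfp_effect)))
    rows.append((exp_id, rnd, well_name(), "CCT2", "", ROLE_CCT2,
                 config.cct2_effect, noisy(config.cct2_effect)))
    for rec in constructs.itertuples():
        rows.append((exp_id, rnd, well_name(), rec.gene, rec.construct_id,
                     ROLE_TEST, rec.true_effect, noisy(rec.true_effect)))
    return pd.DataFrame(
        rows,
        columns=["experiment_id", "round", "well", "gene", "construct_id",
                 "role", "true_effect", "raw_pct"],
    )


def _passes_control_qc(exp: pd.DataFrame, gfp_max: float = 80.0,
                       cct2_min: float = 120.0) -> bool:
    scr = exp.loc[exp.role == ROLE_SCR, "raw_pct"].mean()
    gfp = exp.loc[exp.role == ROLE_GFP, "raw_pct"].iloc[0]
    cct2 = exp.loc[exp.role == ROLE_CCT2, "raw_pct"].iloc[0]
    return (100 * gfp / scr <= gfp_max) and (100 * cct2 / scr >= cct2_min)


def simulate_screen(config: ScreenSimConfig, redo_failed_qc: bool = True) -> ScreenDataset:
    """Simulate a full screen: round-1 plus confirmation experiments.

    Every experiment contains each construct once and the control wells.
    When ``redo_failed_qc`` is set, an experiment whose GFP/CCT2 controls
    land on the wrong side of the default QC bounds is redrawn, mirroring
    the bench practice of repeating experiments with failed controls.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = [f"gene{g:04d}" for g in range(config.n_genes)]
    n_sup = int(round(config.frac_true_suppressors * config.n_genes))
    sup_idx = set(rng.choice(config.n_genes, size=n_sup, replace=False).tolist())

    truth_rows = []
    for gi, gene in enumerate(genes):
        if isinstance(config.constructs_per_gene, int):
            n_con = config.constructs_per_gene
        else:
            n_con = int(rng.choice([1, 2, 3], p=list(config.constructs_per_gene)))
        status = "suppressor" if gi in sup_idx else "null"
        for ci in range(1, n_con + 1):
            if status == "suppressor":
                eff = max(1.0, float(rng.normal(config.effect_mean, config.effect_sd)))
            else:
                eff = config.null_mean
            truth_rows.append({"gene": gene, "construct_id": f"sh{ci}",
                               "status": status, "true_effect": eff})
    truth = pd.DataFrame(truth_rows)

    exp_plan = [(f"R1.{i+1}" if config.n_round1_experiments > 1 else "R1", "round1")
                for i in range(config.n_round1_experiments)]
    exp_plan += [(f"C{i+1}", "confirm") for i in range(config.n_confirm_repeats)]

    frames = []
    for exp_id, rnd in exp_plan:
        for attempt in range(100):
            exp = _experiment_wells(exp_id, rnd, truth, config, rng)
            if not redo_failed_qc or _passes_control_qc(exp):
                break
        else:  # pragma: no cover - would need pathological noise levels
            raise RuntimeError(f"experiment {exp_id} failed control QC 100 times")
        frames.append(exp)

    wells = pd.concat(frames, ignore_index=True)
    return ScreenDataset(wells=wells, truth=truth, config=config)
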