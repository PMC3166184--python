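"""Parameter containers for every pipeline stage.

Defaults encode the screen design: 150% induction cutoff, 0.20 minimum
homology score, 40% identity summary threshold, 5 fields per well, one
round-1 pass followed by triplicate confirmation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import yaml


class ConfigError(ValueError):
    """A configuration value violates a stated invariant."""


@dataclass
class ProteomeSimConfig:
    """Toy proteome pair with planted ortholog/paralog structure.

    ``ortholog_divergence`` is the fraction of residues substituted between
    a source gene and its true target-organism ortholog;
    ``paralog_divergence`` the fraction substituted between within-organism
    paralogs. Truth is only recoverable when paralogs diverge more than
    orthologs, so the generator rejects configs that break that ordering.
    """

    n_families: int = 20
    family_size_range: tuple[int, int] = (1, 3)
    seq_length_range: tuple[int, int] = (120, 240)
    ortholog_divergence: float = 0.2
    paralog_divergence: float = 0.5
    frac_unmappable: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.n_families < 1:
            raise ConfigError("n_families must be >= 1")
        if not self.paralog_divergence > self.ortholog_divergence:
            raise ConfigError(
                "paralog_divergence must exceed ortholog_divergence; "
                "otherwise the planted orthology is not recoverable"
            )
        if not 0.0 <= self.ortholog_divergence <= 1.0:
            raise ConfigError("ortholog_divergence must lie in [0, 1]")
        if not 0.0 <= self.paralog_divergence <= 1.0:
            raise ConfigError("paralog_divergence must lie in [0, 1]")
        if not 0.0 <= self.frac_unmappable <= 1.0:
            raise ConfigError("frac_unmappable must lie in [0, 1]")
        lo, hi = self.family_size_range
        if lo < 1 or hi < lo:
            raise ConfigError("family_size_range must satisfy 1 <= min <= max")
        lo, hi = self.seq_length_range
        if lo < 10 or hi < lo:
            raise ConfigError("seq_length_range must satisfy 10 <= min <= max")


@dataclass
class FieldSimConfig:
    """One rendered two-channel microscope field.

    Channel 1 holds DAPI-like nuclei, channel 2 diffuse GFP per cell plus
    one bright compact aggregate in ``aggregate_fraction`` of the cells.
    Intensities are arbitrary units on a 16-bit-like scale.
    """

    image_shape: tuple[int, int] = (256, 256)
    n_cells: int = 20
    aggregate_fraction: float = 0.3
    nucleus_radius_px: tuple[float, float] = (6.0, 0.8)   # mean, sd
    aggregate_radius_px: tuple[float, float] = (2.5, 0.4)  # mean, sd
    psf_sigma_px: float = 1.0
    background_level: float = 100.0
    noise_sd: float = 5.0
    nucleus_amplitude: float = 2000.0
    diffuse_amplitude: float = 300.0
    aggregate_contrast: float = 5.0   # aggregate peak as multiple of diffuse
    allow_overlap: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < 0:
            raise ConfigError("n_cells must be >= 0")
        if not 0.0 <= self.aggregate_fraction <= 1.0:
            raise ConfigError("aggregate_fraction must lie in [0, 1]")
        if min(self.image_shape) < 32:
            raise ConfigError("image_shape must be at least 32x32")
        if self.aggregate_contrast < 3.0:
            raise ConfigError(
                "aggregate_contrast must be >= 3 so aggregates are "
                "operationally detectable above the diffuse signal"
            )
        for name in ("psf_sigma_px", "background_level", "noise_sd",
                     "nucleus_amplitude", "diffuse_amplitude"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")


@dataclass
class ScreenSimConfig:
    """Plate-level screen with planted per-construct effects.

    Raw well values are ``baseline_pct * true_effect * lognormal noise``
    with coefficient of variation ``measurement_cv``. Every experiment
    carries SCR wells (effect 1), a GFP-knockdown control (effect < 1) and
    a CCT2-knockdown control (effect > 1). One round-1 measurement per
    construct; ``n_confirm_repeats`` confirmation experiments.
    """

    n_genes: int = 50
    constructs_per_gene: int | tuple[float, float, float] = 3
    frac_true_suppressors: float = 0.2
    effect_mean: float = 2.2
    effect_sd: float = 0.25
    null_mean: float = 1.0
    measurement_cv: float = 0.15
    baseline_pct: float = 8.0
    n_fields_per_well: int = 5
    n_scr_wells: int = 2
    gfp_effect: float = 0.5
    cct2_effect: float = 2.0
    n_round1_experiments: int = 1
    n_confirm_repeats: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if isinstance(self.constructs_per_gene, int):
            if not 1 <= self.constructs_per_gene <= 3:
                raise ConfigError("constructs_per_gene must be 1, 2 or 3")
        else:
            probs = tuple(self.constructs_per_gene)
            if len(probs) != 3 or any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
                raise ConfigError(
                    "constructs_per_gene must be an int in 1..3 or a "
                    "3-tuple of probabilities summing to 1"
                )
        if not 0.0 <= self.frac_true_suppressors <= 1.0:
            raise ConfigError("frac_true_suppressors must lie in [0, 1]")
        if self.measurement_cv < 0:
            raise ConfigError("measurement_cv must be >= 0")
        if self.baseline_pct <= 0:
            raise ConfigError("baseline_pct must be > 0")
        if self.n_scr_wells < 1:
            raise ConfigError("at least one SCR well per experiment required")
        if not self.gfp_effect < 1.0 < self.cct2_effect:
            raise ConfigError("controls must satisfy gfp_effect < 1 < cct2_effect")
        if self.n_confirm_repeats < 1 or self.n_round1_experiments < 1:
            raise ConfigError("experiment counts must be >= 1")


@dataclass
class ScoringParams:
    """Pairwise global-alignment scoring for orthology assignment."""

    matrix: str = "BLOSUM62"
    gap_open: float = -11.0
    gap_extend: float = -1.0
    min_score: float = 0.20        # normalized homology-score cutoff
    identity_threshold: float = 40.0  # percent, for the summary


@dataclass
class QuantParams:
    """Quantification recipe parameters (ImageJ-macro equivalent).

    Thresholds are computed relative to image statistics, so counts are
    invariant under a positive rescaling of the intensities.
    """

    smooth_sigma: float = 1.0
    nucleus_min_area: int = 20
    nucleus_max_area: int = 2000
    separation_min_distance: int = 5   # px between watershed seed peaks
    contrast_snr: float = 3.0          # (fg-bg mean gap)/bg sd to accept objects
    aggregate_tophat_radius: int = 6
    aggregate_min_area: int = 2
    aggregate_max_area: int = 300
    aggregate_peak_min_distance: int = 3  # px between distinct spot maxima
    aggregate_min_contrast: float = 1.6  # multiple of diffuse-GFP amplitude
    expected_fields_per_well: int = 5


@dataclass
class QCThresholds:
    """Control acceptance bounds on the SCR=100 scale."""

    gfp_max: float = 80.0
    cct2_min: float = 120.0


@dataclass
class CallParams:
    """Selection-cascade cutoffs."""

    induction_cutoff: float = 150.0
    min_positive_constructs: int = 2
    n_confirm_repeats: int = 3


@dataclass
class RunConfig:
    """Top-level pipeline configuration (YAML-serializable)."""

    seed: int = 0
    outdir: str = "results/run"
    simulate_proteomes: bool = True
    simulate_screen: bool = True
    render_images: bool = False
    proteome: ProteomeSimConfig = field(default_factory=ProteomeSimConfig)
    field_sim: FieldSimConfig = field(default_factory=FieldSimConfig)
    screen: ScreenSimConfig = field(default_factory=ScreenSimConfig)
    scoring: ScoringParams = field(default_factory=ScoringParams)
    quant: QuantParams = field(default_factory=QuantParams)
    qc: QCThresholds = field(default_factory=QCThresholds)
    calls: CallParams = field(default_factory=CallParams)
    source_fasta: str | None = None
    target_fasta: str | None = None
    wells_csv: str | None = None       # pre-quantified per-well percentages
    image_dir: str | None = None       # pre-rendered field images + plate map

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        sub = {
            "proteome": ProteomeSimConfig,
            "field_sim": FieldSimConfig,
            "screen": ScreenSimConfig,
            "scoring": ScoringParams,
            "quant": QuantParams,
            "qc": QCThresholds,
            "calls": CallParams,
        }
        kwargs: dict[str, Any] = {}
        for key, val in d.items():
            if key in sub and isinstance(val, dict):
                val = _coerce_tuples(sub[key], val)
                kwargs[key] = sub[key](**val)
            else:
                kwargs[key] = val
        unknown = set(kwargs) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def _coerce_tuples(dc_type: type, values: dict[str, Any]) -> dict[str, Any]:
    # YAML round-trips tuples as lists; restore them where the field expects one
    out = dict(values)
    for name, f in dc_type.__dataclass_fields__.items():
        if name in out and isinstance(out[name], list) and "tuple" in str(f.type):
            out[name] = tuple(out[name])
    return out
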