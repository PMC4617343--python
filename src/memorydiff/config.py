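"""Simulation and pipeline configuration objects.

The synthetic fixture bundle emulates a two-species parasitic-wasp brain
RNA-seq experiment: one species sampled over three conditioning regimes
(two long-term-memory inductions plus an anesthesia-resistant-memory
control) at three post-conditioning time points, the other over a single
long-term-memory regime, each with an unconditioned reference group and
three biological replicates (30 and 12 libraries respectively).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import yaml

STRUCTURAL_CLASSES = (
    "sense",
    "antisense_to_protein",
    "antisense_to_sense",
    "lncRNA",
    "unknown",
)

EFFECT_ROLES = (
    "ltm_only",
    "arm_only",
    "shared_same_direction",
    "opposing",
    "splice_specific",
)


class ConfigError(ValueError):
    """Raised when a simulation or pipeline configuration is inconsistent."""


@dataclass
class DesignDescriptor:
    """Sampling design of one species: groups = conditioning type x time point."""

    species: str
    conditioning_types: Sequence[str]
    time_points: Mapping[str, Sequence[str]]
    n_replicates: int = 3
    include_unconditioned: bool = True
    unconditioned_label: str = "unconditioned"

    def n_samples(self) -> int:
        n_groups = sum(len(self.time_points[t]) for t in self.conditioning_types)
        if self.include_unconditioned:
            n_groups += 1
        return n_groups * self.n_replicates

    def groups(self) -> list[tuple[str, str]]:
        """All (conditioning_type, time_point) groups, reference last."""
        out = [
            (ct, tp)
            for ct in self.conditioning_types
            for tp in self.time_points[ct]
        ]
        if self.include_unconditioned:
            out.append((self.unconditioned_label, "none"))
        return out

    def validate(self) -> None:
        if self.n_replicates < 2:
            raise ConfigError("n_replicates must be >= 2")
        for ct in self.conditioning_types:
            if ct not in self.time_points or not self.time_points[ct]:
                raise ConfigError(f"no time points given for {ct!r}")


@dataclass
class EffectSpec:
    """A planted expression effect shared by a set of genes.

    role
        ltm_only / arm_only / shared_same_direction / opposing /
        splice_specific — how the affected genes behave across the
        long-term-memory (LTM) conditioning types versus the
        anesthesia-resistant-memory (ARM) control type.
    conditioning_types
        conditioning types carrying the effect; for ``opposing`` and
        ``splice_specific`` the ARM type must be included.
    time_points
        time points affected within each type (None = all).
    log2fc
        magnitude of the planted fold change (sign drawn per gene).
    n_genes
        number of genes assigned this role.
    """

    role: str
    conditioning_types: Sequence[str]
    log2fc: float
    n_genes: int
    time_points: Sequence[str] | None = None

    def validate(self) -> None:
        if self.role not in EFFECT_ROLES:
            raise ConfigError(f"unknown effect role {self.role!r}")
        if not (self.log2fc == self.log2fc and abs(self.log2fc) < float("inf")):
            raise ConfigError("log2fc must be finite")
        if self.n_genes < 0:
            raise ConfigError("n_genes must be >= 0")


@dataclass
class SimulationConfig:
    seed: int = 0
    n_genes: int = 400
    multi_transcript_fraction: float = 0.24
    class_proportions: Mapping[str, float] = field(
        default_factory=lambda: {
            "sense": 0.60,
            "antisense_to_protein": 0.05,
            "antisense_to_sense": 0.03,
            "lncRNA": 0.10,
            "unknown": 0.22,
        }
    )
    design: DesignDescriptor = field(default_factory=lambda: species_a_design())
    library_size_range: tuple[int, int] = (1_000_000, 5_000_000)
    baseline_logmean_sd: float = 1.5
    dispersion_phi0: float = 0.1
    dispersion_a: float = 1.0
    block_effect_sd: float = 0.1
    planted_effects: Sequence[EffectSpec] = field(default_factory=list)
    boundary_margin: float = 0.02
    n_decoys: int = 12

    def validate(self) -> None:
        total = sum(self.class_proportions.get(c, 0.0) for c in STRUCTURAL_CLASSES)
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(
                f"class_proportions must sum to 1 (got {total!r})"
            )
        for cls, frac in self.class_proportions.items():
            if cls not in STRUCTURAL_CLASSES:
                raise ConfigError(f"unknown structural class {cls!r}")
            if not 0.0 <= frac <= 1.0:
                raise ConfigError(f"proportion for {cls!r} outside [0,1]")
        if not 0.0 <= self.multi_transcript_fraction <= 1.0:
            raise ConfigError("multi_transcript_fraction outside [0,1]")
        if not 0.0 < self.boundary_margin < 0.05:
            raise ConfigError("boundary_margin must lie in (0, 0.05)")
        if self.baseline_logmean_sd <= 0 or self.dispersion_phi0 <= 0:
            raise ConfigError("baseline_logmean_sd and dispersion_phi0 must be > 0")
        if self.dispersion_a < 0 or self.block_effect_sd < 0:
            raise ConfigError("dispersion_a and block_effect_sd must be >= 0")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ConfigError("library_size_range must satisfy 0 < lo <= hi")
        self.design.validate()
        for eff in self.planted_effects:
            eff.validate()
            for ct in eff.conditioning_types:
                if ct not in self.design.conditioning_types:
                    raise ConfigError(
                        f"effect references unknown conditioning type {ct!r}"
                    )


GLO_LTM_SHORT = "Glo-LTM-short"
GLO_LTM_LONG = "Glo-LTM-long"
GLO_ARM = "Glo-ARM"
RUB_LTM_LONG = "Rub-LTM-long"


def species_a_design() -> DesignDescriptor:
    """C. glomerata-style design: 3 conditioning types x 3 time points
    plus unconditioned controls, 3 replicates = 30 samples."""
    tps = ["15m", "1h", "4h"]
    return DesignDescriptor(
        species="speciesA",
        conditioning_types=[GLO_LTM_SHORT, GLO_LTM_LONG, GLO_ARM],
        time_points={GLO_LTM_SHORT: tps, GLO_LTM_LONG: tps, GLO_ARM: tps},
        n_replicates=3,
    )


def species_b_design() -> DesignDescriptor:
    """C. rubecula-style design: 1 conditioning type x 3 time points
    plus unconditioned controls, 3 replicates = 12 samples."""
    return DesignDescriptor(
        species="speciesB",
        conditioning_types=[RUB_LTM_LONG],
        time_points={RUB_LTM_LONG: ["1h", "4h", "24h"]},
        n_replicates=3,
    )


def default_effects_a(n_per_role: int = 16, log2fc: float = 2.0) -> list[EffectSpec]:
    """Planted effect catalogue for the species-A design covering every
    comparison rule: LTM-specific, ARM-specific, shared-same-direction,
    opposing-direction, and splice-variant-specific genes."""
    ltm = [GLO_LTM_SHORT, GLO_LTM_LONG]
    return [
        EffectSpec("ltm_only", ltm, log2fc, n_per_role),
        EffectSpec("arm_only", [GLO_ARM], log2fc, n_per_role),
        EffectSpec("shared_same_direction", ltm + [GLO_ARM], log2fc, n_per_role),
        EffectSpec("opposing", ltm + [GLO_ARM], log2fc, n_per_role),
        EffectSpec("splice_specific", ltm + [GLO_ARM], log2fc, n_per_role),
    ]


def default_config_a(seed: int = 0, n_genes: int = 400) -> SimulationConfig:
    cfg = SimulationConfig(
        seed=seed,
        n_genes=n_genes,
        design=species_a_design(),
        planted_effects=default_effects_a(),
    )
    cfg.validate()
    return cfg


def default_config_b(seed: int = 1, n_genes: int = 300) -> SimulationConfig:
    cfg = SimulationConfig(
        seed=seed,
        n_genes=n_genes,
        design=species_b_design(),
        planted_effects=[EffectSpec("ltm_only", [RUB_LTM_LONG], 2.0, 16)],
    )
    cfg.validate()
    return cfg


def _design_from_dict(d: Mapping) -> DesignDescriptor:
    return DesignDescriptor(
        species=d["species"],
        conditioning_types=list(d["conditioning_types"]),
        time_points={k: list(v) for k, v in d["time_points"].items()},
        n_replicates=int(d.get("n_replicates", 3)),
        include_unconditioned=bool(d.get("include_unconditioned", True)),
        unconditioned_label=d.get("unconditioned_label", "unconditioned"),
    )


def simulation_config_from_dict(d: Mapping) -> SimulationConfig:
    kwargs = dict(d)
    if "design" in kwargs:
        kwargs["design"] = _design_from_dict(kwargs["design"])
    if "planted_effects" in kwargs:
        kwargs["planted_effects"] = [
            EffectSpec(
                role=e["role"],
                conditioning_types=list(e["conditioning_types"]),
                log2fc=float(e["log2fc"]),
                n_genes=int(e["n_genes"]),
                time_points=list(e["time_points"]) if e.get("time_points") else None,
            )
            for e in kwargs["planted_effects"]
        ]
    if "library_size_range" in kwargs:
        kwargs["library_size_range"] = tuple(kwargs["library_size_range"])
    cfg = SimulationConfig(**kwargs)
    cfg.validate()
    return cfg


def load_simulation_config(path) -> SimulationConfig:
    with open(path) as fh:
        return simulation_config_from_dict(yaml.safe_load(fh))


def dump_simulation_config(cfg: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=False)
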