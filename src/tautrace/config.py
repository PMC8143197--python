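"""Configuration objects for the synthetic seeding experiment.

A :class:`SimulationConfig` fully determines one simulated condition: a set
of replicate wells of biosensor-expressing neurons imaged on a fixed frame
grid after addition of a tau-seed-containing (or control) brain lysate.
Stochastic behaviour is controlled entirely by ``rng_seed``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

#: Morphologic aggregate archetypes the simulator can render.  "Toxic" is a
#: legal label for interoperability with externally scored data but has no
#: rendering archetype and is never generated.
MORPHOLOGIES = ("Ordered", "Disordered", "Speckles", "Other")

LINE_LABELS = ("control", "mutant")
LYSATE_TYPES = ("seed", "control", "none")

#: Reference dose (µg of total lysate protein per well) at which
#: ``onset_base_hazard_per_h`` applies; the hazard scales as
#: ``(dose / 10)**onset_hazard_dose_exponent``.
REFERENCE_DOSE_UG = 10.0


@dataclass
class SimulationConfig:
    """Parameters of one simulated imaging condition.

    Hazards are per-hour rates of piecewise-constant exponential clocks.
    ``onset_base_hazard_per_h`` is the aggregation-onset hazard of the
    control line at the 10 µg reference dose; the mutant line multiplies it
    by ``onset_hazard_line_multiplier`` and the dose scales it by
    ``(dose_ug / 10)**onset_hazard_dose_exponent``.  Control lysate and the
    no-lysate condition never seed (onset hazard 0), matching the observed
    absence of biosensor aggregation without seed-competent tau.
    """

    n_wells: int = 1
    frames: int = 84                      # 7 d at one frame / 2 h
    frame_interval_h: float = 2.0
    image_size_px: int = 256
    pixel_size_um: float = 0.65
    n_cells_per_well: int = 50
    line_label: str = "control"
    lysate_type: str = "seed"
    dose_ug: float = 10.0
    t0_offset_h: float = 2.0              # seed addition -> first frame (<= one interval)

    onset_base_hazard_per_h: float = 0.004
    onset_hazard_line_multiplier: float = 2.0
    onset_hazard_dose_exponent: float = 1.0
    death_base_hazard_per_h: float = 0.0015
    death_post_onset_multiplier: float = 4.0
    ordered_death_multiplier: float = 1.0  # extra post-onset hazard, Ordered strain
    exit_hazard_per_h: float = 0.0005
    transient_prob: float = 0.05
    transient_dwell_mean_h: float = 30.0
    neurite_seed_rate_per_h: float = 0.12
    max_neurite_seeds_per_cell: int = 12

    morphology_mix: tuple[float, float, float, float] = (0.45, 0.35, 0.10, 0.10)

    death_flash_fold: float = 8.0
    punctum_amplitude_gray: float = 15000.0
    soma_amplitude_gray: float = 6000.0
    neurite_amplitude_gray: float = 1200.0
    nuclear_amplitude_gray: float = 3000.0
    noise_sigma_gray: float = 500.0
    background_gray: float = 1000.0

    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        if self.frames < 2:
            raise ValueError("frames must be >= 2")
        if self.image_size_px <= 0:
            raise ValueError("image_size_px must be positive")
        if self.pixel_size_um <= 0 or self.frame_interval_h <= 0:
            raise ValueError("calibration must be strictly positive")
        if not 0.0 <= self.t0_offset_h <= self.frame_interval_h:
            raise ValueError("t0_offset_h must lie within one frame interval")
        if self.line_label not in LINE_LABELS:
            raise ValueError(f"line_label must be one of {LINE_LABELS}")
        if self.lysate_type not in LYSATE_TYPES:
            raise ValueError(f"lysate_type must be one of {LYSATE_TYPES}")
        if self.dose_ug < 0:
            raise ValueError("dose_ug must be >= 0")
        for name in (
            "onset_base_hazard_per_h",
            "death_base_hazard_per_h",
            "exit_hazard_per_h",
            "death_post_onset_multiplier",
            "onset_hazard_line_multiplier",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        mix = tuple(self.morphology_mix)
        if len(mix) != len(MORPHOLOGIES) or any(p < 0 for p in mix):
            raise ValueError("morphology_mix must be 4 non-negative probabilities")
        if abs(sum(mix) - 1.0) > 1e-9:
            raise ValueError("morphology_mix must sum to 1")
        if not 0.0 <= self.transient_prob <= 1.0:
            raise ValueError("transient_prob must be a probability")

    # ------------------------------------------------------------------
    @property
    def onset_hazard_per_h(self) -> float:
        """Effective aggregation-onset hazard for this condition."""
        if self.lysate_type != "seed" or self.dose_ug <= 0:
            return 0.0
        mult = (
            self.onset_hazard_line_multiplier
            if self.line_label == "mutant"
            else 1.0
        )
        scale = (self.dose_ug / REFERENCE_DOSE_UG) ** self.onset_hazard_dose_exponent
        return self.onset_base_hazard_per_h * mult * scale

    @property
    def horizon_h(self) -> float:
        """Time of the last frame, hours post seed addition."""
        return self.t0_offset_h + (self.frames - 1) * self.frame_interval_h

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["morphology_mix"] = list(self.morphology_mix)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "morphology_mix" in d:
            d["morphology_mix"] = tuple(d["morphology_mix"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)
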