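"""Run configuration: every analysis threshold in one place.

Defaults are the values the analyses are defined with (length bounds
18/40 nt, 10/30 nt RPKM exclusion, 30 RpM pause floor with a 2-fold rule,
50 RpM / 5-fold build-up criteria at 30 min, t=0 RPKM > 100 run-off
filter, 150 nt minimum ORF, 500 nt control distance, >= 4 contiguous SD
matches).  Stage code takes thresholds from here — no magic numbers.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field


@dataclass
class RunConfig:
    # paths (optional; subcommands validate what they need)
    genome: str | None = None
    annotation: str | None = None
    alignments: list[str] = field(default_factory=list)
    sample_sheet: str | None = None
    out_dir: str = "chlororibo_out"
    # read filtering
    length_min: int = 18
    length_max: int = 40
    # RPKM exclusion windows (nt from segment 5'/3')
    exclude_start_nt: int = 10
    exclude_stop_nt: int = 30
    # pause comparison
    pause_min_rpm: float = 30.0
    pause_min_fold: float = 2.0
    pause_min_comparisons: int = 2
    # build-up caller
    buildup_min_rpm: float = 50.0
    buildup_min_fold: float = 5.0
    buildup_t_final_min: float = 30.0
    # run-off
    runoff_min_t0_rpkm: float = 100.0
    block_codons: int = 7
    # annotation / site search
    min_orf_len: int = 150
    control_min_distance: int = 500
    sd_min_match: int = 4
    sd_gap: tuple[int, int] = (4, 14)
    start_window: tuple[int, int] = (9, 18)
    # position assignment
    position_semantics: str = "three_prime_end"
    three_prime_offset: int = 15
    p_site_fallback_offset: int = 12
    offset_min_support: int = 10
    rpkm_use_trimmed_length: bool = False
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sd_gap"] = list(self.sd_gap)
        d["start_window"] = list(self.start_window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("sd_gap", "start_window"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def validate(self) -> None:
        if self.length_min > self.length_max:
            raise ValueError("length_min must be <= length_max")
        for name in ("pause_min_rpm", "pause_min_fold", "buildup_min_rpm",
                     "buildup_min_fold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.position_semantics not in (
                "three_prime_end", "p_site", "p_site_from_three_prime"):
            raise ValueError(
                f"unknown position_semantics {self.position_semantics!r}")
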