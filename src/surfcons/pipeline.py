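"""End-to-end orchestration: structures -> SASA -> conservation ->
variant profiles -> group statistics, from a single flat config.

Outputs are deterministic for a given config and seed: per-structure SASA
tables, per-MSA conservation tables, the variant profile table, the
group-comparison JSON and a run manifest (config echo, stage timings,
package version).  Timings live only in the manifest so the data outputs
are byte-stable.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .conservation import SiteRateModel
from .errors import ConfigError, DataError, SurfconsError
from .sasa import SasaParams, sasa_profile, write_sasa_profile
from .stats import GroupedSample, kruskal_wallis, plot_group_summary
from .structure_io import read_structure
from .variants import (
    NumberingMap,
    group_values_from_profiles,
    profile_variants,
    read_variant_table,
)

logger = logging.getLogger("surfcons")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Flat, fully serialisable run configuration."""

    structures_dir: str = ""
    msas: dict = field(default_factory=dict)  # msa_id -> {"msa": path, "tree": path}
    variant_tables: list = field(default_factory=list)
    numbering_map: str = ""
    output_dir: str = "surfcons-run"
    # SASA engine
    probe_radius: float = 1.4
    n_points: int = 960
    burial_threshold_pct: float = 5.0
    radii_set: str = "chothia1976"
    # conservation
    gamma_shape: float = 1.0
    n_categories: int = 8
    grade_trim: float = 0.025
    # stats
    pairwise_adjust: str = "none"
    make_plot: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text()) or {}
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    def sasa_params(self) -> SasaParams:
        return SasaParams(
            probe=self.probe_radius,
            n_points=self.n_points,
            burial_threshold=self.burial_threshold_pct,
            radii_name=self.radii_set,
        )

    def validate(self) -> None:
        if not self.variant_tables:
            raise ConfigError("config lists no variant tables")
        for p in self.variant_tables:
            if not Path(p).is_file():
                raise ConfigError(f"variant table not found: {p}")
        if not self.numbering_map or not Path(self.numbering_map).is_file():
            raise ConfigError(f"numbering map not found: {self.numbering_map!r}")
        if self.structures_dir and not Path(self.structures_dir).is_dir():
            raise ConfigError(f"structures dir not found: {self.structures_dir}")
        for msa_id, entry in self.msas.items():
            for key in ("msa", "tree"):
                if key not in entry or not Path(entry[key]).is_file():
                    raise ConfigError(
                        f"msa {msa_id!r}: missing or absent {key} file"
                    )
        if self.probe_radius < 0 or self.n_points < 16:
            raise ConfigError("invalid SASA engine parameters")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns a result dict and writes the report
    bundle into ``config.output_dir``."""
    config.validate()
    out = Path(config.output_dir)
    timings: dict[str, float] = {}
    params = config.sasa_params()

    def stage(name):
        logger.info("stage %s", name)
        return time.perf_counter()

    try:
        # --- structures + SASA -------------------------------------------
        t0 = stage("sasa")
        structures = {}
        sasa_profiles = {}
        if config.structures_dir:
            for pdb in sorted(Path(config.structures_dir).glob("*.pdb")):
                st = read_structure(pdb)
                structures[st.id] = st
                sasa_profiles[st.id] = sasa_profile(st, params)
        timings["sasa"] = time.perf_counter() - t0

        # --- conservation -------------------------------------------------
        t0 = stage("conservation")
        conservation = {}
        for msa_id, entry in config.msas.items():
            model = SiteRateModel.from_files(
                entry["msa"],
                entry["tree"],
                gamma_shape=config.gamma_shape,
                n_categories=config.n_categories,
                trim=config.grade_trim,
            )
            conservation[msa_id] = model.fit()
        timings["conservation"] = time.perf_counter() - t0

        # --- variants ------------------------------------------------------
        t0 = stage("profile")
        numbering = NumberingMap.from_file(config.numbering_map)
        variants = []
        for table in config.variant_tables:
            variants.extend(read_variant_table(table))
        profiles, report = profile_variants(
            variants, structures, sasa_profiles, conservation, numbering, params
        )
        timings["profile"] = time.perf_counter() - t0

        # --- statistics ----------------------------------------------------
        t0 = stage("stats")
        values = group_values_from_profiles(profiles)
        comparisons = {}
        for measure, groups in values.items():
            nonempty = {k: v for k, v in groups.items() if len(v)}
            if len(nonempty) >= 2:
                comparisons[measure] = kruskal_wallis(GroupedSample(nonempty))
        timings["stats"] = time.perf_counter() - t0
    except ConfigError:
        raise
    except SurfconsError as exc:
        raise DataError(f"pipeline stage failed: {exc}") from exc

    # --- report bundle ----------------------------------------------------
    out.mkdir(parents=True, exist_ok=True)
    (out / "sasa").mkdir(exist_ok=True)
    for sid, prof in sasa_profiles.items():
        write_sasa_profile(prof, out / "sasa" / f"{sid}.tsv")
    (out / "conservation").mkdir(exist_ok=True)
    for msa_id, result in conservation.items():
        result.to_tsv(out / "conservation" / f"{msa_id}.tsv")
    report.to_csv(out / "profile.tsv", sep="\t", index=False,
                  float_format="%.4f")
    stats_payload = {m: c.to_dict() for m, c in comparisons.items()}
    (out / "stats.json").write_text(json.dumps(stats_payload, indent=2,
                                               sort_keys=True, default=float))
    manifest = {
        "package_version": __version__,
        "config": asdict(config),
        "engine": {"probe": params.probe, "n_points": params.n_points,
                   "burial_threshold_pct": params.burial_threshold,
                   "radii_set": params.radii_name},
        "n_structures": len(structures),
        "n_variants": len(profiles),
        "timings_s": timings,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True, default=float))
    (out / "config.yaml").write_text(config.to_yaml())
    if config.make_plot and comparisons:
        plot_group_summary(comparisons, path=str(out / "group_summary.png"))

    return {
        "structures": structures,
        "sasa_profiles": sasa_profiles,
        "conservation": conservation,
        "profiles": profiles,
        "report": report,
        "comparisons": comparisons,
        "manifest": manifest,
    }
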