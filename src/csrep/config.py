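"""Configuration-driven pipeline: simulate -> summarize -> diff -> eval.

A run is described by a plain YAML mapping (or an in-memory dict).  The
pipeline executes the configured stages in order, writes every artifact
under one output directory, and records a manifest with the config hash,
seed, package version and a checksum per output file, so a rerun with the
same config reproduces bit-identical results.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .differential import differential_scores
from .evaluation import leave_one_out
from .genome import (
    GenomeIndex,
    SampleGroup,
    StateScheme,
    read_chrom_sizes,
    read_segmentation,
    write_score_tracks,
    write_state_bed,
)
from .simulate import GeneratorConfig, generate_differential_pair
from .summarize import argmax_state_map, base_count_summary, summarize_group

__all__ = ["RunConfig", "ConfigError", "run_pipeline", "load_group_dir"]


class ConfigError(ValueError):
    """A configuration problem detected before any computation starts."""


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    Parameter defaults are the method's standard operating point: 200-bp
    bins, a 10% training fraction and L2 strength 1.0.
    """

    out_dir: Path
    seed: int = 0
    bin_size: int = 200
    fraction: float = 0.1
    l2_strength: float = 1.0
    method: str = "csrep"
    chrom_sizes: Path | None = None
    states: int | Path | None = None  # S or a mnemonics file
    group_dirs: dict[str, Path] = field(default_factory=dict)
    simulate: dict[str, Any] | None = None
    diff: tuple[str, str] | None = None  # (group1_id, group2_id)
    eval_loo: list[str] = field(default_factory=list)  # group ids

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError("config file must contain a YAML mapping")
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        known = {
            "out_dir", "seed", "bin_size", "fraction", "l2_strength", "method",
            "chrom_sizes", "states", "group_dirs", "simulate", "diff", "eval_loo",
        }
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        if "out_dir" not in raw:
            raise ConfigError("missing required config field: out_dir")
        cfg = cls(
            out_dir=Path(raw["out_dir"]),
            seed=int(raw.get("seed", 0)),
            bin_size=int(raw.get("bin_size", 200)),
            fraction=float(raw.get("fraction", 0.1)),
            l2_strength=float(raw.get("l2_strength", 1.0)),
            method=str(raw.get("method", "csrep")),
            chrom_sizes=Path(raw["chrom_sizes"]) if raw.get("chrom_sizes") else None,
            states=raw.get("states"),
            group_dirs={k: Path(v) for k, v in (raw.get("group_dirs") or {}).items()},
            simulate=raw.get("simulate"),
            diff=tuple(raw["diff"]) if raw.get("diff") else None,
            eval_loo=list(raw.get("eval_loo") or []),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.method not in ("csrep", "base_count"):
            raise ConfigError(f"method must be 'csrep' or 'base_count', got {self.method!r}")
        if not 0 < self.fraction <= 1:
            raise ConfigError("fraction must be in (0, 1]")
        if self.bin_size <= 0:
            raise ConfigError("bin_size must be positive")
        if self.l2_strength <= 0:
            raise ConfigError("l2_strength must be positive")
        if self.group_dirs and self.simulate is None:
            if self.chrom_sizes is None:
                raise ConfigError("missing required config field: chrom_sizes "
                                  "(needed to bin BED segmentations)")
            if self.states is None:
                raise ConfigError("missing required config field: states")
            for gid, d in self.group_dirs.items():
                if not Path(d).is_dir():
                    raise ConfigError(f"group_dirs[{gid}]: {d} is not a directory")
            if self.chrom_sizes is not None and not Path(self.chrom_sizes).is_file():
                raise ConfigError(f"chrom_sizes: {self.chrom_sizes} not found")
        if self.simulate is None and not self.group_dirs:
            raise ConfigError("nothing to do: provide group_dirs or a simulate section")
        if self.diff is not None:
            if len(self.diff) != 2:
                raise ConfigError("diff must name exactly two groups")

    def canonical(self) -> str:
        d = {
            "out_dir": str(self.out_dir), "seed": self.seed, "bin_size": self.bin_size,
            "fraction": self.fraction, "l2_strength": self.l2_strength,
            "method": self.method,
            "chrom_sizes": str(self.chrom_sizes) if self.chrom_sizes else None,
            "states": str(self.states) if self.states is not None else None,
            "group_dirs": {k: str(v) for k, v in sorted(self.group_dirs.items())},
            "simulate": self.simulate, "diff": list(self.diff) if self.diff else None,
            "eval_loo": self.eval_loo,
        }
        return json.dumps(d, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:16]


def _resolve_scheme(states: int | str | Path) -> StateScheme:
    if isinstance(states, int) or (isinstance(states, str) and states.isdigit()):
        return StateScheme.from_n_states(int(states))
    return StateScheme.from_file(states)


def load_group_dir(
    directory: str | Path,
    index: GenomeIndex,
    scheme: StateScheme,
    group_id: str | None = None,
    fill_state: int | None = None,
) -> SampleGroup:
    """Read every ``*.bed`` file in a directory as one sample's segmentation
    (sorted by filename for a deterministic member order)."""
    directory = Path(directory)
    beds = sorted(directory.glob("*.bed"))
    if not beds:
        raise ConfigError(f"no .bed files found in {directory}")
    members = [read_segmentation(p, index, scheme, fill_state=fill_state) for p in beds]
    return SampleGroup(group_id=group_id or directory.name, members=members)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_group_beds(group: SampleGroup, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    for m in group.members:
        write_state_bed(m.states, m.index, m.scheme, out / f"{m.sample_id}.bed")


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the output directory.

    Stage order: simulate (optional) -> summarize every group -> diff
    (optional) -> leave-one-out eval (optional).  A ``manifest.json`` with
    the config hash, seed, version and per-file checksums is written last.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    groups: dict[str, SampleGroup] = {}
    if config.simulate is not None:
        sim_kwargs = dict(config.simulate)
        sim_kwargs.setdefault("seed", config.seed)
        sim_kwargs.setdefault("bin_size", config.bin_size)
        if "planted_regions" in sim_kwargs:
            sim_kwargs["planted_regions"] = tuple(
                tuple(r) for r in sim_kwargs["planted_regions"])
        gen = GeneratorConfig(**sim_kwargs)
        truth = generate_differential_pair(gen)
        groups[truth.group1.group_id] = truth.group1
        groups[truth.group2.group_id] = truth.group2
        index, scheme = truth.group1.index, truth.group1.scheme
        sim_dir = out / "simulated"
        sim_dir.mkdir(parents=True, exist_ok=True)
        (sim_dir / "chrom.sizes").write_text(
            "".join(f"{n}\t{l}\n" for n, l in index.chromosomes))
        for g in (truth.group1, truth.group2):
            _write_group_beds(g, sim_dir / g.group_id)
        write_state_bed(truth.consensus1, index, scheme, sim_dir / "consensus1.bed")
        write_state_bed(truth.consensus2, index, scheme, sim_dir / "consensus2.bed")
        np.savetxt(sim_dir / "planted_mask.txt", truth.planted_mask, fmt="%d")
        for p in sorted(sim_dir.rglob("*")):
            if p.is_file():
                outputs[str(p.relative_to(out))] = _sha256(p)
    else:
        index = read_chrom_sizes(config.chrom_sizes, bin_size=config.bin_size)
        scheme = _resolve_scheme(config.states)
        for gid, d in config.group_dirs.items():
            groups[gid] = load_group_dir(d, index, scheme, group_id=gid)

    summaries = {}
    for gid, group in groups.items():
        if config.method == "csrep":
            summary = summarize_group(group, fraction=config.fraction,
                                      seed=config.seed, l2_strength=config.l2_strength)
        else:
            summary = base_count_summary(group)
        summaries[gid] = summary
        gdir = out / f"summary_{gid}"
        gdir.mkdir(parents=True, exist_ok=True)
        summary.to_tsv(gdir / "summary_matrix.tsv")
        write_state_bed(argmax_state_map(summary), index, scheme, gdir / "summary_map.bed")
        write_score_tracks(summary.probs, index, scheme, gdir, prefix="prob_")
        for p in sorted(gdir.iterdir()):
            outputs[str(p.relative_to(out))] = _sha256(p)

    if config.diff is not None:
        g1, g2 = config.diff
        for gid in (g1, g2):
            if gid not in summaries:
                raise ConfigError(f"diff names unknown group {gid!r}")
        dm = differential_scores(summaries[g1], summaries[g2])
        ddir = out / f"diff_{g1}_vs_{g2}"
        write_score_tracks(dm.scores, index, scheme, ddir, prefix="diff_")
        np.savetxt(ddir / "diff_matrix.tsv", dm.scores, delimiter="\t", fmt="%.6f",
                   header="\t".join(scheme.names), comments="")
        for p in sorted(ddir.iterdir()):
            outputs[str(p.relative_to(out))] = _sha256(p)

    for gid in config.eval_loo:
        if gid not in groups:
            raise ConfigError(f"eval_loo names unknown group {gid!r}")
        report = leave_one_out(groups[gid], method=config.method,
                               fraction=config.fraction, seed=config.seed,
                               l2_strength=config.l2_strength)
        p = out / f"loo_{gid}.tsv"
        report.table.to_csv(p, sep="\t", index=False)
        outputs[str(p.relative_to(out))] = _sha256(p)

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "outputs": outputs,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
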