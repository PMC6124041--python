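"""End-to-end orchestration: generate/load -> pose -> ROM trials -> statistics.

A :class:`RunConfig` fully determines a run; every run emits its effective
configuration alongside the numeric outputs so any result can be traced to,
and reproduced from, the config and seed that made it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import circstats, mesh_io, rom, synthetic
from .errors import ParameterError

__all__ = ["RunConfig", "ResultBundle", "run_pipeline"]


@dataclass
class RunConfig:
    """Everything needed to reproduce one analysis run.

    Exactly one input source is used: an external angle table (statistics
    only), a column manifest (measured meshes), or a synthetic column spec.
    """

    manifest: str | None = None
    angle_table: str | None = None
    synthetic_spec: dict = field(default_factory=dict)
    modes: tuple[str, ...] = ("PCVM", "MISM")
    epsilon_mm: float = 0.1
    tol_deg: float = 0.01
    bracket_deg: float = 90.0
    presweep_deg: float = 1.0
    contact_included: list[list[str]] | str = "*"
    contact_excluded: list[list[str]] = field(default_factory=list)
    penetration_cap_mm: float = 1.0
    seed: int = 0
    out_dir: str = "vertrom_out"
    make_plots: bool = False

    def contact_rule(self) -> rom.ContactRule:
        included = (
            "*"
            if self.contact_included == "*"
            else frozenset(tuple(p) for p in self.contact_included)
        )
        return rom.ContactRule(
            included=included,
            excluded=frozenset(tuple(p) for p in self.contact_excluded),
            epsilon=self.epsilon_mm,
            penetration_cap=self.penetration_cap_mm,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.modes = tuple(cfg.modes)
        return cfg

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls.from_dict(data)


@dataclass
class ResultBundle:
    """Outputs of one pipeline run."""

    rom_tables: dict[str, rom.ROMTable]
    angle_table: pd.DataFrame
    summary: pd.DataFrame
    p_matrix: pd.DataFrame
    ww_results: dict
    paths: dict[str, Path]


def _column_from_config(config: RunConfig):
    if config.manifest:
        manifest = mesh_io.ColumnManifest.from_json(config.manifest)
        column = mesh_io.load_column(manifest, base_dir=Path(config.manifest).parent)
        return column, manifest.gaps, set(manifest.damage)
    spec_kwargs = dict(config.synthetic_spec)
    base = synthetic.VertebraParams(**spec_kwargs.pop("base", {}))
    gradient = synthetic.GradientSpec(**spec_kwargs.pop("gradient", {}))
    damage = {int(k): tuple(v) for k, v in spec_kwargs.pop("damage", {}).items()}
    gap = spec_kwargs.pop("gap", 2.0)
    spec = synthetic.ColumnSpec(
        base=dataclasses.replace(base, seed=config.seed),
        gradient=gradient,
        damage=damage,
        gap=tuple(gap) if isinstance(gap, (list, tuple)) else float(gap),
        **spec_kwargs,
    )
    column, gaps = synthetic.make_column(spec)
    damaged_ids = {column[i].id for i in damage}
    return column, gaps, damaged_ids


def run_pipeline(config: RunConfig) -> ResultBundle:
    """Run the configured analysis and write all outputs under ``out_dir``.

    With mesh input (manifest or synthetic spec) the requested trials are run
    and their per-joint angle tables feed the statistics; with an external
    angle table only the statistics stage runs.  Bracket-limited searches are
    censored observations, not measured maxima, so they are excluded from the
    statistical groups (they remain in the ROM tables, flagged).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance = {"config": config.to_dict()}
    paths: dict[str, Path] = {}
    rom_tables: dict[str, rom.ROMTable] = {}

    if config.angle_table:
        angle_df = mesh_io.read_angle_table(config.angle_table)
    else:
        column, gaps, damaged_ids = _column_from_config(config)
        rule = config.contact_rule()
        frames = []
        for mode in config.modes:
            table = rom.run_trial(
                column,
                gaps,
                mode,
                rule=rule,
                tol_deg=config.tol_deg,
                bracket=config.bracket_deg,
                presweep=config.presweep_deg,
                damaged_ids=damaged_ids,
            )
            rom_tables[mode] = table
            paths[f"rom_{mode}"] = mesh_io.write_results(
                table, out / f"rom_{mode.lower()}.csv", provenance
            )
            df = table.to_dataframe()
            frames.append(df[~df["missing"] & ~df["bracket_limited"]])
        angle_df = pd.concat(frames, ignore_index=True)[
            ["joint", "profile", "trial", "angle_deg"]
        ]

    paths["angles"] = mesh_io.write_results(angle_df, out / "angles.csv", provenance)
    samples = circstats.samples_from_table(angle_df)
    summary = circstats.summary_table(samples)
    paths["summary"] = out / "summary.csv"
    summary.to_csv(paths["summary"])

    if len(samples) >= 2:
        p_matrix, ww_results = circstats.compare_all(samples)
        paths["tests"] = out / "watson_williams.csv"
        circstats.significance_marks(p_matrix).to_csv(paths["tests"])
        paths["tests_raw"] = out / "watson_williams_p.csv"
        p_matrix.to_csv(paths["tests_raw"])
    else:
        p_matrix, ww_results = pd.DataFrame(), {}

    paths["config"] = out / "run_config.json"
    paths["config"].write_text(json.dumps(provenance["config"], indent=2))

    if config.make_plots:
        paths["figure"] = _boxplot(samples, out / "mobility_profiles.png")

    return ResultBundle(
        rom_tables=rom_tables,
        angle_table=angle_df,
        summary=summary,
        p_matrix=p_matrix,
        ww_results=ww_results,
        paths=paths,
    )


def _boxplot(samples, path: Path) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    ax.boxplot(
        [s.angles_deg for s in samples],
        tick_labels=[s.label for s in samples],
        showmeans=True,
    )
    ax.set_ylabel("intervertebral ROM (deg)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
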