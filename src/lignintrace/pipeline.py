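"""Pipeline orchestration: validated study configuration, staged execution
(simulate -> 1D quantification -> 2D quantification), and report rendering.

A study config lists samples (either generative models or spectrum files)
plus the analyses to run on them; ``run_pipeline`` executes everything
deterministically for a fixed seed and returns a :class:`StudyReport` that
serializes to JSON (schema shipped as package data).
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .io import read_spectrum_1d, read_csv_2d
from .quant1d import analyze_incorporation, deconvolve_gs
from .quant2d import composition, dnp_enhancement, fold_changes
from .shifts import default_shift_table, load_shift_table, quantification_probes
from .synth import SampleModel, simulate_1d, simulate_2d, simulate_dnp_pair

log = logging.getLogger("lignintrace")

_HEADER = "# lignintrace synthetic reconstruction\n"


class SampleEntry(BaseModel):
    name: str
    role: str = Field("labeled", pattern="^(labeled|control)$")
    genotype: str = "WT"
    precursor: str = ""
    tissue: str = "root"
    model: Optional[SampleModel] = None
    path: Optional[str] = None
    noise: float = Field(0.0, ge=0.0)
    control: Optional[str] = None  # name of the paired unlabeled control
    deconv: bool = False

    @model_validator(mode="after")
    def _has_source(self) -> "SampleEntry":
        if self.model is None and self.path is None:
            raise ValueError(f"sample {self.name}: needs a model or a path")
        return self


class DNPEntry(BaseModel):
    name: str
    base: str  # sample whose spectrum is enhanced
    epsilon: float = Field(..., ge=1.0)


class FoldChangePair(BaseModel):
    mutant: str
    wt: str


class StudyConfig(BaseModel):
    seed: int = 0
    shift_table: Optional[str] = None
    samples: list[SampleEntry]
    composition_2d: list[str] = Field(default_factory=list)
    fold_change_pairs: list[FoldChangePair] = Field(default_factory=list)
    dnp: list[DNPEntry] = Field(default_factory=list)

    @model_validator(mode="after")
    def _cross_refs(self) -> "StudyConfig":
        if not self.samples:
            raise ValueError("empty sample list")
        names = [s.name for s in self.samples]
        if len(set(names)) != len(names):
            raise ValueError("duplicate sample names")
        by_name = {s.name: s for s in self.samples}
        for s in self.samples:
            if s.role == "labeled":
                if s.control is None:
                    raise ValueError(f"labeled sample {s.name}: no control reference")
                if s.control not in by_name or by_name[s.control].role != "control":
                    raise ValueError(
                        f"labeled sample {s.name}: control {s.control!r} missing"
                    )
        for name in self.composition_2d:
            if name not in by_name:
                raise ValueError(f"composition_2d references unknown sample {name!r}")
        for pair in self.fold_change_pairs:
            for name in (pair.mutant, pair.wt):
                if name not in self.composition_2d:
                    raise ValueError(
                        f"fold-change sample {name!r} not in composition_2d"
                    )
        for entry in self.dnp:
            if entry.base not in by_name:
                raise ValueError(f"dnp entry {entry.name}: unknown base {entry.base!r}")
        return self


class IncorporationRecord(BaseModel):
    sample: str
    control: str
    aromatic_integral: float
    norm_peak: float
    index: float
    labeling_pct: float


class DeconvRecord(BaseModel):
    sample: str
    g_fa_pct: float
    s_pct: float
    g_center: float
    s_center: float
    residual_norm: float
    converged: bool


class CompositionRecord(BaseModel):
    sample: str
    percent: dict[str, float]
    volumes: dict[str, float]
    total: float


class FoldChangeRecord(BaseModel):
    mutant: str
    wt: str
    ratios: dict[str, float]
    flags: dict[str, str]


class DNPRecord(BaseModel):
    name: str
    base: str
    epsilon: float
    time_saving: float


class Provenance(BaseModel):
    config_sha256: str
    seed: int
    version: str


class StudyReport(BaseModel):
    incorporation: list[IncorporationRecord] = Field(default_factory=list)
    deconvolution: list[DeconvRecord] = Field(default_factory=list)
    composition: list[CompositionRecord] = Field(default_factory=list)
    fold_change: list[FoldChangeRecord] = Field(default_factory=list)
    dnp: list[DNPRecord] = Field(default_factory=list)
    provenance: Provenance


def _sample_seed(base: int, index: int) -> int:
    return int((base * 10007 + 7919 * (index + 1)) % (2**31))


def run_pipeline(config: StudyConfig) -> StudyReport:
    """Execute all configured stages; deterministic for a fixed seed."""
    table = (
        load_shift_table(config.shift_table) if config.shift_table else default_shift_table()
    )
    probes = quantification_probes(table)
    spectra_1d = {}
    by_name = {s.name: s for s in config.samples}
    for i, s in enumerate(config.samples):
        if s.path is not None:
            log.info("stage=load sample=%s path=%s", s.name, s.path)
            spectra_1d[s.name] = read_spectrum_1d(s.path)
        else:
            seed = _sample_seed(config.seed, i)
            log.info("stage=simulate sample=%s seed=%d noise=%g", s.name, seed, s.noise)
            spectra_1d[s.name] = simulate_1d(
                s.model, table=table, noise=s.noise, seed=seed, label=s.name
            )

    report = StudyReport(
        provenance=Provenance(
            config_sha256=hashlib.sha256(
                config.model_dump_json().encode()
            ).hexdigest(),
            seed=config.seed,
            version=__version__,
        )
    )

    for s in config.samples:
        if s.role != "labeled":
            continue
        a = s.model.natural_abundance if s.model is not None else 0.011
        res = analyze_incorporation(spectra_1d[s.name], spectra_1d[s.control], a=a)
        log.info("stage=quant1d sample=%s index=%.3f p=%.2f%%",
                 s.name, res.index, res.labeling_pct)
        report.incorporation.append(
            IncorporationRecord(
                sample=s.name, control=s.control,
                aromatic_integral=res.aromatic_integral, norm_peak=res.norm_peak,
                index=res.index, labeling_pct=res.labeling_pct,
            )
        )
        if s.deconv:
            dres = deconvolve_gs(spectra_1d[s.name])
            report.deconvolution.append(
                DeconvRecord(
                    sample=s.name,
                    g_fa_pct=dres.percent["G/FA"], s_pct=dres.percent["S"],
                    g_center=dres.components["G/FA"]["center"],
                    s_center=dres.components["S"]["center"],
                    residual_norm=dres.residual_norm, converged=dres.converged,
                )
            )

    comp_results = {}
    for j, name in enumerate(config.composition_2d):
        s = by_name[name]
        if s.model is None:
            raise ValueError(f"2D composition for {name}: needs a generative model")
        seed = _sample_seed(config.seed, 1000 + j)
        spec2d = simulate_2d(s.model, table=table, noise=s.noise, seed=seed)
        comp = composition(spec2d, probes=probes, table=table)
        comp_results[name] = comp
        log.info("stage=quant2d sample=%s percent=%s", name,
                 {u: round(v, 1) for u, v in comp.percent.items()})
        report.composition.append(
            CompositionRecord(
                sample=name, percent=comp.percent, volumes=comp.volumes,
                total=comp.total,
            )
        )

    for pair in config.fold_change_pairs:
        fc = fold_changes(comp_results[pair.mutant], comp_results[pair.wt])
        report.fold_change.append(
            FoldChangeRecord(
                mutant=pair.mutant, wt=pair.wt, ratios=fc.ratios, flags=fc.flags
            )
        )

    for k, entry in enumerate(config.dnp):
        base = by_name[entry.base]
        seed = _sample_seed(config.seed, 2000 + k)
        on, off = simulate_dnp_pair(
            spectra_1d[entry.base], entry.epsilon, noise=base.noise, seed=seed
        )
        dnp = dnp_enhancement(on, off)
        log.info("stage=dnp name=%s epsilon=%.2f", entry.name, dnp.epsilon)
        report.dnp.append(
            DNPRecord(
                name=entry.name, base=entry.base,
                epsilon=dnp.epsilon, time_saving=dnp.time_saving,
            )
        )
    return report


def contour_levels(start_frac: float = 0.02, factor: float = 1.07, n: int = 24) -> np.ndarray:
    """Geometric contour-level sequence (fraction of maximum intensity)."""
    if start_frac <= 0 or factor <= 1.0 or n < 1:
        raise ValueError("need start_frac > 0, factor > 1, n >= 1")
    return start_frac * factor ** np.arange(n)


def _write_table(df: pd.DataFrame, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(_HEADER)
        df.to_csv(fh, index=False)


def render_tables(report: StudyReport, outdir) -> list[Path]:
    """Write the report as CSV tables; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, rows: list[dict]) -> None:
        if not rows:
            return
        path = outdir / name
        _write_table(pd.DataFrame(rows), path)
        written.append(path)

    emit("incorporation.csv", [r.model_dump() for r in report.incorporation])
    emit("deconvolution.csv", [r.model_dump() for r in report.deconvolution])
    emit(
        "composition.csv",
        [
            {"sample": r.sample, **{f"{u}_pct": v for u, v in r.percent.items()}}
            for r in report.composition
        ],
    )
    emit(
        "fold_changes.csv",
        [
            {
                "mutant": r.mutant, "wt": r.wt,
                **{f"r_{u}": v for u, v in r.ratios.items()},
                **{f"flag_{u}": f for u, f in r.flags.items() if f},
            }
            for r in report.fold_change
        ],
    )
    emit("dnp.csv", [r.model_dump() for r in report.dnp])
    (outdir / "report.json").write_text(report.model_dump_json(indent=2))
    written.append(outdir / "report.json")
    return written
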