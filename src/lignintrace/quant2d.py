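"""2D cross-peak volumetrics: molar composition of the 13C-labeled lignin
fraction, genotype fold changes, and DNP enhancement accounting.

Composition follows ``X(%) = I_X / I_total * 100`` where ``I_X`` is the
multiplicity-normalized cross-peak volume of unit X in {G, S, H, FA} and
``I_total = I_G + I_S + I_H + I_FA``.  The estimates are semiquantitative:
they reflect the relative proportions of lignin that incorporated 13C from
the supplied precursor, not absolute lignin content.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .shifts import (
    CrossPeakDef,
    ShiftTable,
    SpectralRegion,
    default_shift_table,
    named_regions,
    pair_multiplicity,
    quantification_probes,
)
from .synth import Spectrum1D, Spectrum2D

DEFAULT_HALF_WIDTH = 1.5  # ppm, per dimension; comparable to the 2D linewidth


@dataclass
class CompositionResult:
    volumes: dict[str, float]  # multiplicity-normalized I_X
    total: float
    percent: dict[str, float]
    peak_table: list[dict] = field(default_factory=list)
    weights: dict[str, float] = field(default_factory=dict)


@dataclass
class FoldChangeResult:
    ratios: dict[str, float]
    flags: dict[str, str]
    normalization: dict[str, float]


@dataclass
class DNPResult:
    epsilon: float
    time_saving: float  # = epsilon**2


def integrate_crosspeak(
    spec: Spectrum2D,
    peak: CrossPeakDef,
    half_width_ppm: float = DEFAULT_HALF_WIDTH,
    allow_diagonal: bool = False,
) -> float:
    """Box integral (sum * pixel area) around a cross-peak position.

    The symmetric twin box at (f2, f1) is averaged in when it also falls
    inside the spectral window.  Off-diagonal peaks whose box would overlap
    the diagonal band are rejected unless ``allow_diagonal`` is set.
    """
    if not allow_diagonal and abs(peak.f1_ppm - peak.f2_ppm) < 2.0 * half_width_ppm:
        if peak.f1_ppm != peak.f2_ppm:
            raise ValueError(
                f"box for {peak.name} overlaps the diagonal band; "
                "use allow_diagonal=True for diagonal peaks"
            )

    def box(c1: float, c2: float) -> float | None:
        if (
            c1 - half_width_ppm < spec.f1_ppm[0]
            or c1 + half_width_ppm > spec.f1_ppm[-1]
            or c2 - half_width_ppm < spec.f2_ppm[0]
            or c2 + half_width_ppm > spec.f2_ppm[-1]
        ):
            return None
        m1 = (spec.f1_ppm >= c1 - half_width_ppm) & (spec.f1_ppm <= c1 + half_width_ppm)
        m2 = (spec.f2_ppm >= c2 - half_width_ppm) & (spec.f2_ppm <= c2 + half_width_ppm)
        d1 = float(np.mean(np.diff(spec.f1_ppm)))
        d2 = float(np.mean(np.diff(spec.f2_ppm)))
        return float(spec.intensity[np.ix_(m1, m2)].sum()) * d1 * d2

    main = box(peak.f1_ppm, peak.f2_ppm)
    if main is None:
        raise ValueError(f"box for {peak.name} lies outside the spectral window")
    if peak.f1_ppm == peak.f2_ppm:
        return main
    twin = box(peak.f2_ppm, peak.f1_ppm)
    return main if twin is None else 0.5 * (main + twin)


def composition(
    spec: Spectrum2D,
    probes: dict[str, list[CrossPeakDef]] | None = None,
    table: ShiftTable | None = None,
    half_width_ppm: float = DEFAULT_HALF_WIDTH,
    weights: dict[str, float] | None = None,
) -> CompositionResult:
    """Molar composition of the labeled lignin from diagnostic cross-peaks.

    Each unit's raw volume sum is divided by its multiplicity weight (the
    summed n_a*n_b over its probe peaks) so units probed through different
    numbers of equivalent carbon pairs are comparable.
    """
    if table is None:
        table = default_shift_table()
    if probes is None:
        probes = quantification_probes(table)
    peak_table: list[dict] = []
    norm_volumes: dict[str, float] = {}
    used_weights: dict[str, float] = {}
    for unit, peaks in probes.items():
        if not peaks:
            raise ValueError(f"no probe cross-peak for unit {unit}")
        raw = 0.0
        weight = 0.0
        for peak in peaks:
            v = integrate_crosspeak(spec, peak, half_width_ppm)
            m = pair_multiplicity(table, peak)
            raw += v
            weight += m
            peak_table.append(
                {"unit": unit, "name": peak.name, "site_a": peak.site_a,
                 "site_b": peak.site_b, "f1_ppm": peak.f1_ppm,
                 "f2_ppm": peak.f2_ppm, "volume": v, "multiplicity": m}
            )
        if weights is not None:
            weight = weights[unit]
        norm_volumes[unit] = raw / weight
        used_weights[unit] = weight
    total = sum(norm_volumes.values())
    if total <= 0:
        raise ValueError("all cross-peak volumes are zero")
    percent = {u: 100.0 * v / total for u, v in norm_volumes.items()}
    return CompositionResult(
        volumes=norm_volumes, total=total, percent=percent,
        peak_table=peak_table, weights=used_weights,
    )


def fold_changes(
    mutant: CompositionResult,
    wt: CompositionResult,
    norm: tuple[float, float] | None = None,
) -> FoldChangeResult:
    """Per-unit mutant/WT volume ratios.

    With ``norm=None`` the two samples are normalized to equal total
    aromatic lignin signal, so the ratio reduces to the ratio of molar
    percentages.  ``norm=(mutant_ref, wt_ref)`` normalizes each sample to a
    user-supplied reference volume instead.
    """
    if set(mutant.volumes) != set(wt.volumes):
        raise ValueError("composition results use different unit sets")
    if norm is None:
        n_mut, n_wt = mutant.total, wt.total
    else:
        n_mut, n_wt = norm
        if n_mut <= 0 or n_wt <= 0:
            raise ValueError("normalization volumes must be positive")
    ratios: dict[str, float] = {}
    flags: dict[str, str] = {}
    for unit in mutant.volumes:
        num = mutant.volumes[unit] / n_mut
        den = wt.volumes[unit] / n_wt
        if den == 0.0:
            ratios[unit] = np.inf if num > 0 else np.nan
            flags[unit] = "zero WT volume"
        else:
            ratios[unit] = num / den
            flags[unit] = ""
    return FoldChangeResult(
        ratios=ratios, flags=flags, normalization={"mutant": n_mut, "wt": n_wt}
    )


def dnp_enhancement(
    on: Spectrum1D,
    off: Spectrum1D,
    region: SpectralRegion | None = None,
    noise_floor: float = 0.0,
) -> DNPResult:
    """Enhancement factor epsilon = on/off peak height in a probe region.

    Sensitivity scales linearly with epsilon, so the acquisition time needed
    for a given signal-to-noise drops by epsilon**2.
    """
    if on.ppm.shape != off.ppm.shape or not np.allclose(on.ppm, off.ppm):
        raise ValueError("on/off spectra must share the same axis")
    region = region or named_regions()["carbohydrate_ref"]
    mask = (on.ppm >= region.lo_ppm) & (on.ppm <= region.hi_ppm)
    if not mask.any():
        raise ValueError("probe region outside spectrum axis")
    off_max = float(off.intensity[mask].max())
    if off_max <= noise_floor:
        raise ValueError("off-spectrum maximum does not exceed the noise floor")
    eps = float(on.intensity[mask].max()) / off_max
    return DNPResult(epsilon=eps, time_saving=eps**2)
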