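"""Synthetic Ct data with known ground truth.

The generator emulates the structure of a donor x condition qPCR panel:

    Ct[g, s] = baseline_g + shift_{g, cond(s)} + donor_offset_{donor(s)} + noise

with Normal noise on the Ct (log2-expression) scale — the standard qPCR
error model — additive gene-shared donor offsets, and technical-control
readings (PPC, RTC) drawn around their nominal means. The designed stability
order of the genes (by condition-shift spread plus noise SD) is part of the
output, so ranking pipelines can be tested against a known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import CONDITIONS, ControlReadings, CtTable, ValidationError

#: generated Cts outside this range indicate an unrealistic spec
GENERATED_CT_RANGE = (5.0, 40.0)


@dataclass(frozen=True)
class GeneSim:
    """Ground-truth parameters of one simulated gene: baseline Ct (cycles),
    per-condition additive shifts (cycles; absent conditions shift 0), and
    the SD of its measurement noise (cycles)."""

    name: str
    baseline: float
    shifts: Mapping[str, float] = field(default_factory=dict)
    noise_sd: float = 0.2

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValidationError(f"gene {self.name!r}: noise_sd must be > 0")
        unknown = sorted(set(self.shifts) - set(CONDITIONS))
        if unknown:
            raise ValidationError(f"gene {self.name!r}: unknown conditions {unknown}")

    def perturbation(self) -> float:
        """Total designed perturbation: population SD of the shift profile
        across all conditions plus the noise SD. Lower = designed stabler."""
        deltas = np.array([self.shifts.get(c, 0.0) for c in CONDITIONS])
        return float(deltas.std(ddof=0) + self.noise_sd)


@dataclass(frozen=True)
class ControlSim:
    """Nominal technical-control statistics (cycles)."""

    ppc_mean: float = 18.65
    ppc_sd: float = 0.36
    rtc_mean: float = 22.62
    rtc_sd: float = 0.31


@dataclass(frozen=True)
class SyntheticSpec:
    """Full ground truth for one simulated experiment."""

    genes: tuple[GeneSim, ...]
    n_donors: int = 3
    donor_sd: float = 0.3
    conditions: tuple[str, ...] = CONDITIONS
    controls: ControlSim = field(default_factory=ControlSim)

    def __post_init__(self) -> None:
        if self.n_donors < 1:
            raise ValidationError("need at least one donor")
        if self.donor_sd < 0:
            raise ValidationError("donor_sd must be >= 0")
        names = [g.name for g in self.genes]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate gene names in spec")

    def stability_order(self) -> list[str]:
        """Gene names sorted by designed perturbation, stablest first
        (ties broken alphabetically)."""
        return [
            g.name
            for g in sorted(self.genes, key=lambda g: (g.perturbation(), g.name))
        ]


@dataclass(frozen=True)
class Simulation:
    """Generator output: the clean (final) table, the raw table with the
    control deviations embedded (so technical normalization recovers the
    clean table), the control readings, and the ground truth."""

    table: CtTable  # final Ct values (no technical offsets)
    raw: CtTable  # final + per-sample control deviations
    controls: ControlReadings
    spec: SyntheticSpec
    stability_order: tuple[str, ...]  # designed order, stablest first
    perturbation: pd.Series  # designed perturbation per gene


def paper_like_spec() -> SyntheticSpec:
    """A 5-gene panel shaped like a typical ASC housekeeping study: baseline
    Cts about 18.5-26.3, starvation raising Ct by ~1-2 cycles on the two
    starvation-responsive genes, inflammation a smaller ~0.4, per-gene noise
    0.1-0.3 cycles. HK1 is the designed stablest gene (no shifts, minimal
    noise) and HK5 the least stable.

    Each responsive gene has its own per-condition profile — including one
    gene whose Ct drops under starvation — because genes sharing an identical
    response profile act as a co-regulated pair that pairwise stability
    statistics cannot tell apart from genuinely stable genes.
    """
    return SyntheticSpec(
        genes=(
            GeneSim("HK1", 18.5, {}, 0.10),
            GeneSim("HK2", 19.5, {"S": 1.2, "S+IL1": 1.0, "F+IL1/S": 1.5}, 0.15),
            GeneSim("HK3", 20.3, {"F+IL1": 0.4, "S+IL1": 0.4}, 0.25),
            GeneSim("HK4", 26.3, {"S": -0.4, "S+IL1": -0.4, "F+IL1/S": -0.4}, 0.30),
            GeneSim("HK5", 18.5, {"S": 1.5, "S+IL1": 2.2, "F+IL1/S": 0.6}, 0.30),
        )
    )


def generate(spec: SyntheticSpec, seed: int) -> Simulation:
    """Draw one experiment from ``spec``; byte-identical for equal seeds."""
    rng = np.random.default_rng(seed)
    donors = [f"D{i + 1}" for i in range(spec.n_donors)]
    samples = [f"{d} {c}" for c in spec.conditions for d in donors]
    meta = pd.DataFrame(
        {
            "donor": [s.split(" ", 1)[0] for s in samples],
            "condition": [s.split(" ", 1)[1] for s in samples],
        },
        index=pd.Index(samples, name="sample"),
    )
    donor_offsets = dict(zip(donors, rng.normal(0.0, spec.donor_sd, len(donors))))
    sample_conditions = meta["condition"].to_numpy()
    sample_donor_offset = meta["donor"].map(donor_offsets).to_numpy()

    ct = np.empty((len(samples), len(spec.genes)))
    for j, gene in enumerate(spec.genes):
        shifts = np.array([gene.shifts.get(c, 0.0) for c in sample_conditions])
        noise = rng.normal(0.0, gene.noise_sd, len(samples))
        ct[:, j] = gene.baseline + shifts + sample_donor_offset + noise
    lo, hi = GENERATED_CT_RANGE
    if np.any((ct < lo) | (ct > hi)):
        raise ValidationError(
            f"spec produced Ct values outside {GENERATED_CT_RANGE}; "
            "check baselines/shifts"
        )
    names = [g.name for g in spec.genes]
    clean = CtTable(
        pd.DataFrame(ct, index=meta.index, columns=names),
        meta,
        provenance=(f"simulated seed={seed}",),
    )

    ppc = pd.Series(
        rng.normal(spec.controls.ppc_mean, spec.controls.ppc_sd, len(samples)),
        index=meta.index,
        name="ppc",
    )
    rtc = pd.Series(
        rng.normal(spec.controls.rtc_mean, spec.controls.rtc_sd, len(samples)),
        index=meta.index,
        name="rtc",
    )
    controls = ControlReadings(ppc=ppc, rtc=rtc)
    # raw = clean + per-sample control deviations, so that normalize_technical
    # exactly recovers the clean table
    drift = (ppc - ppc.mean()) + (rtc - rtc.mean())
    raw = CtTable(
        clean.ct.add(drift, axis=0),
        meta,
        provenance=(f"simulated raw (control drift embedded) seed={seed}",),
    )
    perturbation = pd.Series(
        {g.name: g.perturbation() for g in spec.genes}, name="perturbation"
    )
    return Simulation(
        table=clean,
        raw=raw,
        controls=controls,
        spec=spec,
        stability_order=tuple(spec.stability_order()),
        perturbation=perturbation,
    )
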