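"""Technical normalization against PPC and RTC control wells.

Each qPCR plate carries a positive PCR control (PPC, monitoring amplification
efficiency) and a reverse-transcription control (RTC, monitoring cDNA
synthesis efficiency). When those controls are tight across samples, their
per-sample deviation from the cross-sample mean is a technical (not
biological) offset shared by every assay on that sample's plate, and is
subtracted from all gene Cts:

    adjusted Ct = raw Ct - (ppc_s - mean(ppc)) - (rtc_s - mean(rtc))

applied sequentially, PPC first then RTC. Mean-centring the controls keeps
the overall Ct scale: flat controls leave the table untouched, and adding a
constant to every control reading changes nothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import ControlReadings, CtTable, ValidationError


@dataclass(frozen=True)
class NormalizationReport:
    """Control summary statistics (population SD) and the per-sample offsets
    that were subtracted. Offsets for each control sum to zero."""

    ppc_mean: float
    ppc_sd: float
    rtc_mean: float
    rtc_sd: float
    ppc_offsets: pd.Series
    rtc_offsets: pd.Series
    formula: str = (
        "adjusted = raw - (ppc_s - mean(ppc)) - (rtc_s - mean(rtc)), "
        "sequential PPC then RTC"
    )

    def to_dict(self) -> dict:
        return {
            "ppc_mean": self.ppc_mean,
            "ppc_sd": self.ppc_sd,
            "rtc_mean": self.rtc_mean,
            "rtc_sd": self.rtc_sd,
            "ppc_offsets": self.ppc_offsets.to_dict(),
            "rtc_offsets": self.rtc_offsets.to_dict(),
            "formula": self.formula,
        }


def normalize_technical(
    raw: CtTable, controls: ControlReadings
) -> tuple[CtTable, NormalizationReport]:
    """Two-step technical normalization of ``raw`` against PPC then RTC.

    Controls must cover every sample of ``raw``; extra control samples are
    ignored. Returns the adjusted table and a :class:`NormalizationReport`.
    """
    missing = [s for s in raw.samples if s not in controls.ppc.index]
    if missing:
        raise ValidationError(f"missing control readings for samples: {missing}")
    ppc = controls.ppc.loc[raw.samples].astype(float)
    rtc = controls.rtc.loc[raw.samples].astype(float)

    ppc_off = ppc - ppc.mean()
    adjusted = raw.ct.sub(ppc_off, axis=0)
    rtc_off = rtc - rtc.mean()
    adjusted = adjusted.sub(rtc_off, axis=0)

    report = NormalizationReport(
        ppc_mean=float(ppc.mean()),
        ppc_sd=float(ppc.std(ddof=0)),
        rtc_mean=float(rtc.mean()),
        rtc_sd=float(rtc.std(ddof=0)),
        ppc_offsets=ppc_off,
        rtc_offsets=rtc_off,
    )
    table = CtTable(
        adjusted,
        raw.meta,
        raw.provenance + ("technical normalization (PPC then RTC, mean-centred)",),
    )
    return table, report
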