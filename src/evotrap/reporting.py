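"""Per-generation records, replicate containers, cross-replicate summaries, file I/O.

Time series are written as RFC-4180 CSV ('.' decimal, UTF-8) with a fixed
column order, plus a JSON sidecar carrying the full parameter set and seed
provenance so any run can be reproduced from its output directory alone.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .config import ParameterSet, generalist_efficiency
from .genetics import Genotype
from .outcomes import KillTally

__all__ = [
    "GenerationRecord", "ReplicateResult", "GridSummary", "COLUMNS",
    "record_generation", "classify_outcome",
    "write_timeseries", "read_timeseries", "summarize_replicates",
]

#: Fixed CSV column order for time-series output.
COLUMNS = [
    "generation", "H1", "H2", "P",
    "freq_S1", "freq_S2", "freq_S3",
    "mean_q", "sd_q",
    "mean_q_S1", "sd_q_S1", "n_S1",
    "mean_q_S2", "sd_q_S2", "n_S2",
    "mean_q_S3", "sd_q_S3", "n_S3",
    "repro_kills_1", "nonrepro_kills_1", "survived_1", "eggs_laid_1", "emerged_1",
    "repro_kills_2", "nonrepro_kills_2", "survived_2", "eggs_laid_2", "emerged_2",
]


@dataclass(frozen=True)
class GenerationRecord:
    """Census of one generation.

    ``H1``/``H2`` are host counts *after* parasitism (the survivors that
    found the next generation); ``P`` is the number of adult parasitoids that
    foraged this generation.  Strategy frequencies and preference statistics
    describe those adults; per-class q statistics come with the class count
    ``n_S*`` because the mean preference of a rare class is erratic and must
    be read alongside its size.  All statistics are NaN for empty groups.
    """

    generation: int
    H1: int
    H2: int
    P: int
    freq_S1: float
    freq_S2: float
    freq_S3: float
    mean_q: float
    sd_q: float
    mean_q_S1: float
    sd_q_S1: float
    n_S1: int
    mean_q_S2: float
    sd_q_S2: float
    n_S2: int
    mean_q_S3: float
    sd_q_S3: float
    n_S3: int
    repro_kills_1: int
    nonrepro_kills_1: int
    survived_1: int
    eggs_laid_1: int
    emerged_1: int
    repro_kills_2: int
    nonrepro_kills_2: int
    survived_2: int
    eggs_laid_2: int
    emerged_2: int


def record_generation(generation: int, adults: Sequence[Genotype],
                      tally: KillTally, H1: int, H2: int) -> GenerationRecord:
    """Build the census record for one generation from its adult parasitoids."""
    P = len(adults)
    if P > 0:
        q = np.fromiter((g.q for g in adults), dtype=float, count=P)
        S = np.fromiter((g.S for g in adults), dtype=np.int64, count=P)
    else:
        q = np.empty(0)
        S = np.empty(0, dtype=np.int64)

    def _stats(vals: np.ndarray) -> tuple[float, float]:
        if vals.size == 0:
            return math.nan, math.nan
        return float(np.mean(vals)), float(np.std(vals))

    mean_q, sd_q = _stats(q)
    per_class = {}
    for s in (1, 2, 3):
        sel = q[S == s]
        m, sd = _stats(sel)
        per_class[s] = (m, sd, int(sel.size))
    return GenerationRecord(
        generation=generation, H1=H1, H2=H2, P=P,
        freq_S1=per_class[1][2] / P if P else math.nan,
        freq_S2=per_class[2][2] / P if P else math.nan,
        freq_S3=per_class[3][2] / P if P else math.nan,
        mean_q=mean_q, sd_q=sd_q,
        mean_q_S1=per_class[1][0], sd_q_S1=per_class[1][1], n_S1=per_class[1][2],
        mean_q_S2=per_class[2][0], sd_q_S2=per_class[2][1], n_S2=per_class[2][2],
        mean_q_S3=per_class[3][0], sd_q_S3=per_class[3][1], n_S3=per_class[3][2],
        repro_kills_1=tally.reproductive_kills[0],
        nonrepro_kills_1=tally.nonreproductive_kills[0],
        survived_1=tally.survived[0], eggs_laid_1=tally.eggs_laid[0],
        emerged_1=tally.emerged[0],
        repro_kills_2=tally.reproductive_kills[1],
        nonrepro_kills_2=tally.nonreproductive_kills[1],
        survived_2=tally.survived[1], eggs_laid_2=tally.eggs_laid[1],
        emerged_2=tally.emerged[1],
    )


@dataclass
class ReplicateResult:
    """One replicate's full time series plus its provenance."""

    params: ParameterSet
    records: list[GenerationRecord]
    replicate_index: int = 0
    extinction_generation: int | None = None

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame([dataclasses.asdict(r) for r in self.records])
        return df[COLUMNS]

    @property
    def final(self) -> GenerationRecord:
        return self.records[-1]


@dataclass
class GridSummary:
    """Cross-replicate summary of an experimental grid, one row per variant."""

    table: pd.DataFrame
    replicates: int
    results: dict[str, list[ReplicateResult]] | None = None


def classify_outcome(record: GenerationRecord) -> str:
    """Label the evolutionary outcome of a final-generation record.

    ``extinct`` when no parasitoid remains; otherwise the strategy class
    holding a majority (frequency > 0.5); ``polymorphic`` when none does.
    """
    if record.P == 0:
        return "extinct"
    freqs = {"specialist1": record.freq_S1, "specialist2": record.freq_S2,
             "generalist": record.freq_S3}
    best = max(freqs, key=freqs.get)  # type: ignore[arg-type]
    return best if freqs[best] > 0.5 else "polymorphic"


def write_timeseries(result: ReplicateResult, path: str | Path) -> Path:
    """Write one replicate as CSV plus a JSON provenance sidecar.

    The sidecar (same stem, ``.json``) holds the exact parameter set
    (including the master seed), the replicate index, and the extinction
    generation if the parasitoid died out.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    result.to_dataframe().to_csv(path, index=False, lineterminator="\n")
    sidecar = {
        "parameters": result.params.to_dict(),
        "replicate_index": result.replicate_index,
        "extinction_generation": result.extinction_generation,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2) + "\n",
                                         encoding="utf-8")
    return path


def read_timeseries(path: str | Path) -> pd.DataFrame:
    """Read back a time-series CSV written by :func:`write_timeseries`."""
    return pd.read_csv(path)


def summarize_replicates(variants: Sequence[tuple[str, ParameterSet]],
                         results: dict[str, list["ReplicateResult"]]) -> pd.DataFrame:
    """Final-generation summary across replicates, one row per variant.

    Strategy frequencies and per-class mean preference are averaged over the
    replicates whose parasitoid population survived to the final generation;
    ``extinct_fraction`` reports the rest.  Standard errors are sd/sqrt(n)
    over surviving replicates (NaN when n < 2).
    """
    rows = []
    for label, p in variants:
        reps = results[label]
        finals = [r.final for r in reps]
        alive = [f for f in finals if f.P > 0]
        n = len(alive)

        def _mse(attr: str) -> tuple[float, float]:
            vals = np.array([getattr(f, attr) for f in alive], dtype=float)
            vals = vals[~np.isnan(vals)]
            if vals.size == 0:
                return math.nan, math.nan
            se = float(np.std(vals, ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else math.nan
            return float(np.mean(vals)), se

        row: dict = {
            "variant": label,
            "scenario": p.scenario,
            "tau_s": p.tau_s,
            "generalist_efficiency": generalist_efficiency(p),
            "mu_q": p.mu_q,
            "mu_S": p.mu_S,
            "replicates": len(reps),
            "surviving_replicates": n,
            "extinct_fraction": 1.0 - n / len(reps),
        }
        for s in (1, 2, 3):
            m, se = _mse(f"freq_S{s}")
            row[f"mean_freq_S{s}"] = m
            row[f"se_freq_S{s}"] = se
            row[f"mean_q_S{s}"], _ = _mse(f"mean_q_S{s}")
        rows.append(row)
    return pd.DataFrame(rows)
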