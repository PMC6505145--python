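"""Relative copy number from qPCR Ct values (comparative, delta-delta-Ct).

The marker assay is normalized to a housekeeping assay within each sample
(dCt), then to a calibrator sample of known copy number (ddCt); relative
quantity RQ = efficiency^(-ddCt).  With a calibrator carrying
``calibrator_copies_per_genome`` marker copies, the test sample carries
``RQ x calibrator_copies_per_genome`` copies per genome, and dividing by its
number of transgene-bearing alleles gives copies per allele.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from tgarray.screen import CopyNumberEstimate

ASSAY_MARKER = "marker"
ASSAY_HOUSEKEEPING = "housekeeping"


@dataclass(frozen=True)
class CtWell:
    sample_id: str
    assay: str  # marker | housekeeping
    ct: float
    replicate: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.ct < 40:
            raise ValueError(f"Ct {self.ct} outside (0, 40)")
        if self.assay not in (ASSAY_MARKER, ASSAY_HOUSEKEEPING):
            raise ValueError(f"unknown assay {self.assay!r}")


@dataclass(frozen=True)
class SampleDesign:
    sample_id: str
    role: str  # test | calibrator
    calibrator_copies_per_genome: float = 1.0
    test_alleles: int = 1  # 1 heterozygous, 2 homozygous

    def __post_init__(self) -> None:
        if self.test_alleles not in (1, 2):
            raise ValueError("test_alleles must be 1 or 2")


@dataclass
class RelativeQuantity:
    sample_id: str
    rq: float
    sd: Optional[float]
    delta_delta_ct: float
    n_marker_replicates: int


def _cts(wells: Sequence[CtWell], sample: str, assay: str) -> list[float]:
    vals = [w.ct for w in wells if w.sample_id == sample and w.assay == assay]
    if not vals:
        raise ValueError(f"sample {sample!r} has no {assay} wells")
    return vals


def delta_delta_ct(
    wells: Sequence[CtWell],
    test_sample: str,
    calibrator_sample: str,
    efficiency: float = 2.0,
) -> RelativeQuantity:
    """RQ of ``test_sample`` relative to ``calibrator_sample``.

    dCt = mean marker Ct - mean housekeeping Ct per sample; ddCt = dCt_test -
    dCt_cal; RQ = efficiency^(-ddCt).  The SD comes from jackknifing the test
    sample's marker replicates (leave-one-out RQs).
    """
    tm = _cts(wells, test_sample, ASSAY_MARKER)
    th = _cts(wells, test_sample, ASSAY_HOUSEKEEPING)
    cm = _cts(wells, calibrator_sample, ASSAY_MARKER)
    ch = _cts(wells, calibrator_sample, ASSAY_HOUSEKEEPING)
    dct_cal = np.mean(cm) - np.mean(ch)

    def rq_of(marker_cts: Sequence[float]) -> float:
        ddct = (np.mean(marker_cts) - np.mean(th)) - dct_cal
        return float(efficiency ** -ddct)

    rq = rq_of(tm)
    sd = None
    n = len(tm)
    if n > 1:
        loo = np.array([rq_of(tm[:i] + tm[i + 1:]) for i in range(n)])
        sd = float(math.sqrt((n - 1) / n * ((loo - loo.mean()) ** 2).sum()))
    ddct = float((np.mean(tm) - np.mean(th)) - dct_cal)
    return RelativeQuantity(test_sample, rq, sd, ddct, n)


def copies_per_allele(rq: RelativeQuantity | float, design: SampleDesign) -> CopyNumberEstimate:
    """Marker copies per transgene-bearing allele of the test sample."""
    if isinstance(rq, RelativeQuantity):
        val, sd, n = rq.rq, rq.sd, rq.n_marker_replicates
    else:
        val, sd, n = float(rq), None, 0
    if val <= 0:
        raise ValueError("RQ must be > 0")
    scale = design.calibrator_copies_per_genome / design.test_alleles
    return CopyNumberEstimate(
        method="qpcr", value=val * scale,
        dispersion=sd * scale if sd is not None else None, n_support=n)


# ---------------------------------------------------------------------------
# CSV input (sample_id, assay, ct, replicate)

def read_ct_table(path) -> list[CtWell]:
    df = pd.read_csv(path)
    required = {"sample_id", "assay", "ct"}
    if not required <= set(df.columns):
        raise ValueError(f"Ct table needs columns {sorted(required)}")
    if "replicate" not in df.columns:
        df["replicate"] = range(len(df))
    return [CtWell(str(r.sample_id), str(r.assay), float(r.ct), int(r.replicate))
            for r in df.itertuples()]


def read_design_table(path) -> list[SampleDesign]:
    df = pd.read_csv(path)
    out = []
    for r in df.itertuples():
        out.append(SampleDesign(
            str(r.sample_id), str(r.role),
            float(getattr(r, "copies", 1.0)),
            int(getattr(r, "alleles", 1))))
    return out


# ---------------------------------------------------------------------------
# synthetic Ct batches (for tests and recovery studies)

def simulate_ct_batch(
    true_copies_per_allele: float,
    seed: int,
    test_alleles: int = 1,
    calibrator_copies_per_genome: float = 1.0,
    n_replicates: int = 6,
    noise_sd: float = 0.1,
    efficiency: float = 2.0,
    housekeeping_ct: float = 20.0,
    marker_cal_ct: float = 28.0,
) -> tuple[list[CtWell], SampleDesign]:
    """Synthetic wells for one batch with a known true copy number.

    The test sample's marker Ct is shifted from the calibrator's by
    -log_eff(true copies per genome / calibrator copies per genome); every
    well gets i.i.d. Gaussian Ct noise of ``noise_sd`` cycles.
    """
    rng = np.random.default_rng(seed)
    copies_per_genome = true_copies_per_allele * test_alleles
    shift = -math.log(copies_per_genome / calibrator_copies_per_genome, efficiency)
    wells: list[CtWell] = []
    for i in range(n_replicates):
        wells += [
            CtWell("test", ASSAY_MARKER, marker_cal_ct + shift + rng.normal(0, noise_sd), i),
            CtWell("test", ASSAY_HOUSEKEEPING, housekeeping_ct + rng.normal(0, noise_sd), i),
            CtWell("cal", ASSAY_MARKER, marker_cal_ct + rng.normal(0, noise_sd), i),
            CtWell("cal", ASSAY_HOUSEKEEPING, housekeeping_ct + rng.normal(0, noise_sd), i),
        ]
    design = SampleDesign("test", "test", calibrator_copies_per_genome, test_alleles)
    return wells, design
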