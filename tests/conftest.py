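"""Shared builders for handcrafted profiles, probe matrices and thresholds."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from focalamp.io import ProbeMatrix
from focalamp.segmentation import SatThreshold, SegmentProfile


def make_profile(sample: str, segs: list[tuple]) -> SegmentProfile:
    """segs: list of (chrom, start, end, n_probes, mean)."""
    return SegmentProfile(
        sample=sample,
        segments=pd.DataFrame(
            segs, columns=["chrom", "start", "end", "n_probes", "mean"]))


def make_sat(sample: str, tau: float) -> SatThreshold:
    return SatThreshold(sample=sample, tau=tau, noise=tau / 3.0)


def make_pm(values_by_sample: dict[str, np.ndarray], chrom: str = "chr1",
            spacing: int = 1000, probe_len: int = 60) -> ProbeMatrix:
    """Evenly spaced probes on one chromosome, one column per sample."""
    samples = list(values_by_sample)
    n = len(values_by_sample[samples[0]])
    probes = pd.DataFrame({
        "probe_id": [f"p{i:05d}" for i in range(n)],
        "chrom": chrom,
        "start": np.arange(n) * spacing,
        "end": np.arange(n) * spacing + probe_len,
    })
    ratios = np.column_stack([np.asarray(values_by_sample[s], dtype=float)
                              for s in samples])
    return ProbeMatrix(probes, ratios, samples)


@pytest.fixture
def rng():
    return np.random.default_rng(20230618)
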