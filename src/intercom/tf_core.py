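"""Selection of transcription factors whose expression is preserved across a
large fraction of a population's cells."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .expression import PopulationProfile


@dataclass
class PreservedTFSet:
    population: str
    tfs: list[str]  # sorted by expressed fraction descending, ties by symbol
    threshold_fraction: float


def preserved_tfs(
    profile: PopulationProfile,
    regulon_tfs: set[str],
    percentile: float = 0.95,
    mode: str = "distribution",
) -> PreservedTFSet:
    """Select TFs expressed in the top percentile of cells.

    ``mode='distribution'`` keeps TFs whose expressed-cell fraction is at or
    above the ``percentile`` quantile of the TF fraction distribution (linear
    interpolation, inclusive comparison).  ``mode='absolute'`` reads the
    threshold literally: keep TFs expressed in at least ``percentile`` of the
    population's cells.
    """
    measured = sorted(tf for tf in regulon_tfs if profile.has_gene(tf))
    if not measured:
        raise ValidationError(
            f"population {profile.population!r}: no regulon TF is measured"
        )
    fractions = np.array([profile.fraction(tf) for tf in measured])
    if fractions.max() == 0:
        raise ValidationError(
            f"population {profile.population!r}: no TF is expressed in any cell"
        )
    if mode == "distribution":
        cut = float(np.quantile(fractions, percentile))
    elif mode == "absolute":
        cut = float(percentile)
    else:
        raise ValueError(f"unknown tf mode {mode!r}")
    kept = [tf for tf, f in zip(measured, fractions) if f >= cut]
    kept.sort(key=lambda tf: (-profile.fraction(tf), tf))
    return PreservedTFSet(population=profile.population, tfs=kept, threshold_fraction=cut)
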