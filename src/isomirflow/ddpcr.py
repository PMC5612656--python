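"""Droplet digital PCR quantification.

Absolute quantification from droplet partitioning: the number of template
copies per droplet is Poisson, so the fraction of positive droplets f gives
lambda = -ln(1 - f) and the concentration lambda / droplet volume.  Target
concentrations are normalised to a reference gene per sample and expressed
relative to the mean of a designated reference group of samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import math

import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_DROPLET_VOLUME_NL = 0.85  # instrument-typical droplet volume


@dataclass(frozen=True)
class DropletWell:
    sample_id: str
    target_id: str
    n_positive: int
    n_total: int
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL

    def __post_init__(self) -> None:
        if self.n_total < 1:
            raise ValueError("n_total must be >= 1")
        if not 0 <= self.n_positive <= self.n_total:
            raise ValueError("need 0 <= n_positive <= n_total")
        if self.droplet_volume_nl <= 0:
            raise ValueError("droplet volume must be > 0")


def poisson_concentration(well: DropletWell) -> float:
    """Copies per microliter from droplet occupancy.

    lambda = -ln(1 - n_positive / n_total); concentration = lambda / volume,
    with the nanoliter droplet volume converted to microliters.  A saturated
    well (all droplets positive) is rejected; wells with fewer than 10,000
    droplets log a warning.
    """
    if well.n_positive == well.n_total:
        raise ValueError(
            f"well ({well.sample_id}, {well.target_id}) is saturated: "
            "all droplets positive")
    if well.n_total < 10000:
        logger.warning("well (%s, %s) has only %d droplets",
                       well.sample_id, well.target_id, well.n_total)
    lam = -math.log1p(-well.n_positive / well.n_total)
    return lam / (well.droplet_volume_nl * 1e-3)


def _mean_concentration_by_sample(wells) -> dict[str, float]:
    """Average replicate-well concentrations per sample (before any ratio)."""
    acc: dict[str, list[float]] = {}
    for w in wells:
        acc.setdefault(w.sample_id, []).append(poisson_concentration(w))
    return {s: sum(v) / len(v) for s, v in acc.items()}


def normalize_to_reference(target_wells, reference_wells) -> pd.Series:
    """Per-sample ratio of target concentration to reference-gene concentration.

    Replicate wells are averaged on the concentration scale before the ratio
    is taken.  Every sample must have both a target and a reference well, and
    the reference concentration must be non-zero.
    """
    target = _mean_concentration_by_sample(target_wells)
    reference = _mean_concentration_by_sample(reference_wells)
    ratios = {}
    for sample, conc in target.items():
        if sample not in reference:
            raise ValueError(f"sample {sample!r} has no reference-gene well")
        ref = reference[sample]
        if ref == 0:
            raise ValueError(
                f"sample {sample!r}: reference-gene concentration is 0")
        ratios[sample] = conc / ref
    return pd.Series(ratios, name="ratio_to_reference")


def relative_to_group(
    ratios: pd.Series, groups: pd.Series, reference_group_label: str
) -> pd.Series:
    """Express each sample's ratio relative to the reference group's mean.

    The arithmetic mean ratio of the reference group becomes 1 by
    construction.
    """
    in_ref = groups.reindex(ratios.index) == reference_group_label
    if not in_ref.any():
        raise ValueError(f"reference group {reference_group_label!r} is empty")
    ref_mean = ratios[in_ref].mean()
    if ref_mean == 0:
        raise ValueError("reference group mean ratio is 0")
    return (ratios / ref_mean).rename("relative_expression")


def read_wells(path, droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL
               ) -> list[DropletWell]:
    """Read a TSV of wells: sample_id, target_id, n_positive, n_total."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "target_id", "n_positive", "n_total"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        DropletWell(str(r.sample_id), str(r.target_id), int(r.n_positive),
                    int(r.n_total), droplet_volume_nl)
        for r in df.itertuples()
    ]
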