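"""Synthetic-data generators with machine-readable ground truth.

Every input the pipeline consumes can be generated here: miRNA references
(mature + precursor hairpins plus screening references), small-RNA reads in
the eight truth classes, negative-binomial count matrices with a 2x2
genotype x treatment design and spiked log2 fold changes, exponential
survival tables with fixed-time administrative censoring, and binomially
sampled droplet-positive counts under a Poisson occupancy model.

Generators are pure functions of (parameters, seed).  A single integer seed
drives one named pseudo-random stream per generator, so fixtures are
reproducible regardless of the order in which generators are invoked.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import classify as _cls
from .io import CountMatrix, SequenceRecord, SmallRead

BASES = "ACGT"

READ_CLASSES = (
    "identical", "shorter", "end_sub", "end_add",
    "internal_mm", "precursor_only", "contaminant", "junk",
)

# truth class -> (classifier category, subtype) expected for a clean read
_EXPECTED_CALL = {
    "identical": (_cls.C1_IDENTICAL, None),
    "shorter": (_cls.C2_SHORTER, None),
    "end_sub": (_cls.C3_VARIANT, _cls.END_SUBSTITUTION),
    "end_add": (_cls.C3_VARIANT, _cls.END_ADDITION),
    "internal_mm": (_cls.C3_VARIANT, _cls.INTERNAL_MISMATCH),
    "precursor_only": (_cls.C4_PRECURSOR, None),
}


def stream(seed: int, name: str) -> np.random.Generator:
    """A named, independent pseudo-random stream derived from one seed."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


# ---------------------------------------------------------------------------
# references


@dataclass
class ReferenceSet:
    """Mature + precursor miRNA references and the screening references."""

    mature: list[SequenceRecord]
    precursor: list[SequenceRecord]
    coding_exon: list[SequenceRecord] = field(default_factory=list)
    other_smallrna: list[SequenceRecord] = field(default_factory=list)


def simulate_reference(
    n_mirnas: int,
    mature_len_range: tuple[int, int] = (21, 24),
    flank_len: int = 25,
    seed: int = 0,
    max_tries: int = 1000,
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Random mature miRNAs and precursor hairpins that contain them.

    Matures are drawn pairwise distinct and pairwise non-substring by
    rejection sampling (an error is raised if that fails within
    ``max_tries`` per sequence).  Each precursor carries its mature as an
    exact substring with ``flank_len`` random bases on each side, and the
    precursor id equals the mature id so precursor matches can be attributed
    to the right family downstream.
    """
    if n_mirnas < 1:
        raise ValueError("n_mirnas must be >= 1")
    lo, hi = mature_len_range
    if not (18 <= lo <= hi <= 26):
        raise ValueError("mature lengths must lie within [18, 26]")
    rng = stream(seed, "reference")
    matures: list[str] = []
    for i in range(n_mirnas):
        for _ in range(max_tries):
            cand = _random_seq(rng, int(rng.integers(lo, hi + 1)))
            if all(cand not in m and m not in cand and cand != m for m in matures):
                matures.append(cand)
                break
        else:
            raise RuntimeError(
                f"could not draw {n_mirnas} pairwise non-substring matures")
    mature_recs = [
        SequenceRecord(f"syn-mir-{i + 1:04d}", seq) for i, seq in enumerate(matures)
    ]
    precursor_recs = [
        SequenceRecord(
            rec.id,
            _random_seq(rng, flank_len) + rec.sequence + _random_seq(rng, flank_len),
            "precursor",
        )
        for rec in mature_recs
    ]
    return mature_recs, precursor_recs


def simulate_contaminant_reference(
    n_seqs: int = 5,
    length: int = 300,
    seed: int = 0,
    label: str = "contam",
) -> list[SequenceRecord]:
    """Random long sequences standing in for coding exons / other small RNAs."""
    rng = stream(seed, f"contaminants:{label}")
    return [
        SequenceRecord(f"syn-{label}-{i + 1:03d}", _random_seq(rng, length))
        for i in range(n_seqs)
    ]


def simulate_reference_set(
    n_mirnas: int = 40,
    mature_len_range: tuple[int, int] = (21, 24),
    flank_len: int = 25,
    n_exons: int = 5,
    n_other_smallrna: int = 5,
    contaminant_len: int = 300,
    seed: int = 0,
) -> ReferenceSet:
    mature, precursor = simulate_reference(n_mirnas, mature_len_range, flank_len, seed)
    exons = simulate_contaminant_reference(n_exons, contaminant_len, seed, "exon")
    other = simulate_contaminant_reference(
        n_other_smallrna, contaminant_len, seed, "smallrna")
    return ReferenceSet(mature, precursor, exons, other)


# ---------------------------------------------------------------------------
# reads


@dataclass(frozen=True)
class QualityModel:
    """Per-read quality/length corruption applied on top of the class edits.

    A ``low_quality_fraction`` of reads receive qualities around
    ``low_mean_phred`` (mean below 30, so the QC filter rejects them); a
    ``bad_length_fraction`` of *junk* reads get lengths outside [16, 35]
    (length outliers are emulated within the unassignable class because the
    miRNA-derived classes have lengths fixed by their defining edits).
    """

    mean_phred: float = 38.0
    sd_phred: float = 2.0
    low_quality_fraction: float = 0.05
    low_mean_phred: float = 20.0
    bad_length_fraction: float = 0.05


def _qualities(rng: np.random.Generator, n: int, mean: float, sd: float,
               at_least: float | None) -> tuple[int, ...]:
    while True:
        q = np.clip(np.rint(rng.normal(mean, sd, size=n)), 2, 41).astype(int)
        if at_least is None or q.mean() >= at_least:
            return tuple(int(v) for v in q)


def simulate_reads(
    reference: ReferenceSet,
    class_proportions: Mapping[str, float],
    n_reads: int,
    quality_model: QualityModel = QualityModel(),
    seed: int = 0,
    max_tries: int = 50,
) -> tuple[list[SmallRead], pd.DataFrame]:
    """Simulate small-RNA reads of the eight truth classes.

    Per class the generator applies exactly the defining edit (copy, 1-5 base
    trim split over the ends, single end substitution, 1-2 non-templated
    additions, single internal substitution, precursor-junction substring,
    contaminant substring, random junk).  Every miRNA-derived read is
    verified against the classifier's own rules and resampled until its call
    matches its truth label uniquely, so truth labels are consistent with the
    category definitions by construction.  Junk reads are verified to be
    unassigned and to evade contaminant screening.

    Returns the reads plus a truth table with one row per read:
    read_id, source_mirna, true_category, edits, low_quality,
    length_out_of_range.
    """
    props = dict(class_proportions)
    unknown = set(props) - set(READ_CLASSES)
    if unknown:
        raise ValueError(f"unknown read classes: {sorted(unknown)}")
    total = sum(props.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"class proportions sum to {total}, expected 1")
    needs = {
        "contaminant": reference.coding_exon or reference.other_smallrna,
        "precursor_only": reference.precursor,
    }
    for klass, ok in needs.items():
        if props.get(klass, 0) > 0 and not ok:
            raise ValueError(f"class {klass!r} requested but reference absent")
    if any(props.get(k, 0) > 0 for k in READ_CLASSES[:6]) and not reference.mature:
        raise ValueError("miRNA-derived classes requested but mature reference absent")

    rng = stream(seed, "reads")
    index = _cls.build_index(reference.mature, reference.precursor)
    fam_of = {member: f.id for f in index.families for member in f.members}
    classes = list(props)
    draws = rng.choice(len(classes), size=n_reads, p=[props[c] for c in classes])

    reads: list[SmallRead] = []
    truth_rows: list[tuple] = []
    qm = quality_model
    for i, ci in enumerate(draws):
        klass = classes[int(ci)]
        read_id = f"read_{i + 1:06d}"
        seq, source, edits = _make_read_sequence(
            rng, klass, reference, index, fam_of, qm, max_tries)
        low_q = bool(rng.random() < qm.low_quality_fraction)
        bad_len = len(seq) < 16 or len(seq) > 35
        if low_q:
            quals = _qualities(rng, len(seq), qm.low_mean_phred, qm.sd_phred, None)
        else:
            quals = _qualities(rng, len(seq), qm.mean_phred, qm.sd_phred, 30.0)
        reads.append(SmallRead(read_id, seq, quals))
        truth_rows.append((read_id, source, klass, edits, low_q, bad_len))

    truth = pd.DataFrame(
        truth_rows,
        columns=["read_id", "source_mirna", "true_category", "edits",
                 "low_quality", "length_out_of_range"],
    )
    return reads, truth


def _make_read_sequence(rng, klass, reference, index, fam_of, qm, max_tries):
    """Draw one read sequence of the requested class, resampling until the
    classifier agrees with the truth label (and, for junk, until the read is
    unassignable and unscreened)."""
    for _ in range(max_tries):
        if klass == "junk":
            if rng.random() < qm.bad_length_fraction:
                length = int(rng.choice(list(range(10, 16)) + list(range(36, 46))))
            else:
                length = int(rng.integers(16, 36))
            seq, source, edits = _random_seq(rng, length), "none", f"len={length}"
            if _junk_ok(seq, reference, index):
                return seq, source, edits
            continue
        if klass == "contaminant":
            pool = ([("coding_exon", r) for r in reference.coding_exon]
                    + [("other_smallrna", r) for r in reference.other_smallrna])
            kind, ref = pool[int(rng.integers(len(pool)))]
            length = int(rng.integers(16, min(35, len(ref.sequence)) + 1))
            off = int(rng.integers(0, len(ref.sequence) - length + 1))
            seq = ref.sequence[off:off + length]
            # must not simultaneously be a miRNA match, or truth would lie
            if _cls.classify_read(seq, index).category == _cls.UNASSIGNED:
                return seq, "contaminant", f"{kind}={ref.id},offset={off}"
            continue
        # miRNA-derived classes
        mi = int(rng.integers(len(reference.mature)))
        mature = reference.mature[mi]
        m = mature.sequence
        L = len(m)
        if klass == "identical":
            seq, edits = m, "copy"
        elif klass == "shorter":
            t_max = min(5, L - 16)
            t = int(rng.integers(1, t_max + 1))
            t5 = int(rng.integers(0, t + 1))
            seq, edits = m[t5:L - (t - t5)], f"trim5={t5},trim3={t - t5}"
        elif klass == "end_sub":
            p = int(rng.choice([0, L - 1]))
            b = rng.choice([x for x in BASES if x != m[p]])
            seq, edits = m[:p] + b + m[p + 1:], f"pos={p},ref={m[p]},alt={b}"
        elif klass == "end_add":
            total = int(rng.integers(1, 3))
            a5 = int(rng.integers(0, total + 1))
            extra = _random_seq(rng, total)
            seq = extra[:a5] + m + extra[a5:]
            edits = f"add5={a5},add3={total - a5}"
        elif klass == "internal_mm":
            p = int(rng.integers(1, L - 1))
            b = rng.choice([x for x in BASES if x != m[p]])
            seq, edits = m[:p] + b + m[p + 1:], f"pos={p},ref={m[p]},alt={b}"
        elif klass == "precursor_only":
            pre = reference.precursor[mi]
            flank = (len(pre.sequence) - L) // 2
            length = int(rng.integers(16, 36))
            # overlap a mature/flank junction so categories 1-3 cannot apply
            junction = flank if rng.random() < 0.5 else flank + L
            lo = max(0, junction - length + 2)
            hi = min(len(pre.sequence) - length, junction - 2)
            if hi < lo:
                continue
            off = int(rng.integers(lo, hi + 1))
            seq = pre.sequence[off:off + length]
            edits = f"precursor={pre.id},offset={off}"
        else:  # pragma: no cover - guarded upstream
            raise ValueError(klass)
        call = _cls.classify_read(seq, index)
        want_cat, want_sub = _EXPECTED_CALL[klass]
        if (call.category == want_cat and call.subtype == want_sub
                and call.mirna_id == fam_of[mature.id]):
            return seq, mature.id, edits
    raise RuntimeError(
        f"could not generate a verifiable {klass!r} read in {max_tries} tries")


def _junk_ok(seq, reference, index) -> bool:
    if _cls.classify_read(seq, index).category != _cls.UNASSIGNED:
        return False
    from .filtering import _SubstringScreen

    screen = _SubstringScreen(reference.coding_exon + reference.other_smallrna)
    return not screen.contains(seq)


# ---------------------------------------------------------------------------
# count matrices


def simulate_counts(
    design: Mapping[str, tuple[str, str]],
    n_features: int = 2000,
    de_fraction: float = 0.1,
    log2fc_magnitude: float = 2.0,
    dispersion: float = 0.1,
    lib_size_range: tuple[float, float] = (0.5e6, 2e6),
    seed: int = 0,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Negative-binomial counts for a genotype x treatment design.

    Each feature receives a baseline relative abundance (log-normal,
    normalised to sum to one).  Independently per contrast (genotype effect
    and treatment effect) a ``de_fraction`` of features is spiked with a
    signed log2 fold change of magnitude ``log2fc_magnitude``; counts are
    drawn NB with mean = library size x abundance x 2^(effects) and a common
    dispersion (gamma-Poisson mixture, exact for dispersion -> 0).

    Returns the count matrix (sample groups labelled "genotype_treatment")
    and a truth table with per-contrast log2 fold changes and DE flags.
    """
    if not 0 <= de_fraction <= 1:
        raise ValueError("de_fraction must lie in [0, 1]")
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    samples = list(design)
    genotypes = sorted({g for g, _ in design.values()})
    treatments = sorted({t for _, t in design.values()})
    labels = pd.Series({s: f"{g}_{t}" for s, (g, t) in design.items()})
    if labels.nunique() < 2:
        raise ValueError("need at least 2 groups")
    counts_per_group = labels.value_counts()
    if (counts_per_group < 2).any():
        raise ValueError("need >= 2 samples per group")

    rng = stream(seed, "counts")
    abund = rng.lognormal(mean=0.0, sigma=1.5, size=n_features)
    abund /= abund.sum()
    lib_sizes = np.exp(rng.uniform(np.log(lib_size_range[0]),
                                   np.log(lib_size_range[1]), size=len(samples)))

    def spike(contrast_active: bool) -> np.ndarray:
        if not contrast_active:
            return np.zeros(n_features)
        is_de = rng.random(n_features) < de_fraction
        signs = rng.choice([-1.0, 1.0], size=n_features)
        return np.where(is_de, signs * log2fc_magnitude, 0.0)

    lfc_geno = spike(len(genotypes) > 1)
    lfc_trt = spike(len(treatments) > 1)

    mat = np.zeros((n_features, len(samples)), dtype=np.int64)
    for j, s in enumerate(samples):
        g, t = design[s]
        eff = (lfc_geno * (genotypes.index(g)) if len(genotypes) > 1 else 0.0)
        eff = eff + (lfc_trt * (treatments.index(t)) if len(treatments) > 1 else 0.0)
        mu = lib_sizes[j] * abund * np.power(2.0, eff)
        lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
        mat[:, j] = rng.poisson(lam)

    feature_ids = [f"feat_{i + 1:05d}" for i in range(n_features)]
    cm = CountMatrix(pd.DataFrame(mat, index=feature_ids, columns=samples), labels)
    truth = pd.DataFrame(
        {
            "feature_id": feature_ids,
            "log2fc_genotype": lfc_geno,
            "is_de_genotype": lfc_geno != 0,
            "log2fc_treatment": lfc_trt,
            "is_de_treatment": lfc_trt != 0,
            "dispersion": dispersion,
        }
    ).set_index("feature_id")
    return cm, truth


def two_group_design(n_per_group: int, group1: str = "control",
                     group2: str = "treated") -> dict[str, tuple[str, str]]:
    """A single-genotype, two-treatment design (the common 4v4 / 6v6 layout)."""
    design = {}
    for i in range(n_per_group):
        design[f"{group1}_{i + 1}"] = ("wt", group1)
    for i in range(n_per_group):
        design[f"{group2}_{i + 1}"] = ("wt", group2)
    return design


# ---------------------------------------------------------------------------
# survival


def simulate_survival(
    n_per_group: Mapping[str, int],
    hazard_per_group: Mapping[str, float],
    censor_time: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential event times with fixed-time administrative censoring.

    Times beyond ``censor_time`` are recorded censored at ``censor_time``
    (event = False), emulating a study terminated at a fixed postnatal day.
    """
    if censor_time <= 0:
        raise ValueError("censor_time must be > 0")
    for g, h in hazard_per_group.items():
        if h <= 0:
            raise ValueError(f"hazard for group {g!r} must be > 0")
    rng = stream(seed, "survival")
    rows = []
    for group, n in n_per_group.items():
        h = hazard_per_group[group]
        times = rng.exponential(scale=1.0 / h, size=n)
        for i, t in enumerate(times):
            event = t <= censor_time
            rows.append((f"{group}_{i + 1}", group,
                         float(t if event else censor_time), bool(event)))
    return pd.DataFrame(rows, columns=["subject_id", "group", "time", "event"])


# ---------------------------------------------------------------------------
# droplets


def simulate_droplets(
    lambda_per_droplet: float,
    n_droplets: int,
    seed: int = 0,
) -> tuple[int, int]:
    """Binomially sampled positive droplets under Poisson occupancy.

    Each droplet is positive with probability 1 - exp(-lambda).
    """
    if lambda_per_droplet < 0:
        raise ValueError("lambda must be >= 0")
    if n_droplets < 1:
        raise ValueError("n_droplets must be >= 1")
    rng = stream(seed, "droplets")
    p = 1.0 - np.exp(-lambda_per_droplet)
    return int(rng.binomial(n_droplets, p)), n_droplets
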