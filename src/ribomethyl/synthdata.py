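"""Seeded generators for every input the pipeline stages consume.

Each generator is a pure function of its spec and seed: identical seeds give
identical outputs.  The footprint generator realises the stationary A-site
occupancy model directly — it picks an ORF sense codon with probability
proportional to its dwell weight and places the read so that codon sits at
read positions 15-17 — rather than simulating elongation trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._codons import BASES, SENSE_CODONS, STOP_CODONS
from .io_formats import Transcriptome
from .methylquant import MethylPeptideSpec, mz, ppm_window
from .motiflogo import NTerminalPattern

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class DwellModel:
    """Relative A-site residence time per sense codon, with per-condition
    multiplicative overrides (e.g. KO slows AAA/AAG by some factor).

    Unspecified codons default to weight 1.0; all weights must be positive.
    """

    weights: dict[str, float] = field(default_factory=dict)
    condition_overrides: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for codon, w in self.weights.items():
            if w <= 0:
                raise ValueError(f"dwell weight for {codon} must be > 0, got {w}")
        for cond, table in self.condition_overrides.items():
            for codon, m in table.items():
                if m <= 0:
                    raise ValueError(f"override for {codon} in {cond} must be > 0, got {m}")

    def weight_vector(self, condition: str | None = None) -> np.ndarray:
        """Weights over the 61 sense codons in SENSE_CODONS order."""
        w = np.array([self.weights.get(c, 1.0) for c in SENSE_CODONS])
        if condition is not None and condition in self.condition_overrides:
            override = self.condition_overrides[condition]
            w = w * np.array([override.get(c, 1.0) for c in SENSE_CODONS])
        return w


@dataclass
class SimSpec:
    """Desk-scale ribosome-profiling simulation design.

    Read lengths span 28-32 nt; the analysis keeps only 29-31.  A small
    off-frame fraction shifts the 5' end by +/-1 nt, exercising the frame
    filter.  ORF lengths are in codons including start and stop.
    """

    n_transcripts: int = 50
    orf_codons_mean: int = 100
    orf_codons_sd: int = 20
    orf_codons_min: int = 30
    utr5: int = 30
    utr3: int = 30
    n_reads: int = 200_000
    read_length_probs: dict[int, float] = field(
        default_factory=lambda: {28: 0.10, 29: 0.25, 30: 0.30, 31: 0.25, 32: 0.10})
    off_frame_fraction: float = 0.05
    replicates: dict[str, int] = field(default_factory=lambda: {"WT": 2, "KO": 3})
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.read_length_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"read length probabilities must sum to 1, got {total}")
        if not 0 <= self.off_frame_fraction < 1:
            raise ValueError("off_frame_fraction must be in [0, 1)")
        if self.orf_codons_min < 12:
            raise ValueError("ORFs must be at least 12 codons to host a footprint")


def make_transcriptome(spec: SimSpec, usage: dict[str, float] | None = None) -> Transcriptome:
    """Generate transcripts whose ORFs start with ATG, end with a stop, and
    contain no internal stop codon.

    Codon usage over the 61 sense codons is uniform unless ``usage`` is
    supplied (need not be normalized).  Deterministic for a fixed spec.
    """
    rng = np.random.default_rng(spec.seed)
    if usage is None:
        probs = np.full(len(SENSE_CODONS), 1.0 / len(SENSE_CODONS))
    else:
        probs = np.array([usage.get(c, 0.0) for c in SENSE_CODONS], dtype=float)
        if probs.sum() <= 0:
            raise ValueError("usage table assigns no mass to sense codons")
        probs = probs / probs.sum()
    sense = np.array(SENSE_CODONS)
    stops = np.array(STOP_CODONS)
    sequences: dict[str, str] = {}
    orfs: dict[str, tuple[int, int]] = {}
    for i in range(spec.n_transcripts):
        n_codons = max(spec.orf_codons_min, int(round(rng.normal(spec.orf_codons_mean, spec.orf_codons_sd))))
        body = sense[rng.choice(len(sense), size=n_codons - 2, p=probs)]
        orf = "ATG" + "".join(body) + str(stops[rng.integers(len(stops))])
        utr5 = "".join(np.array(list(BASES))[rng.integers(0, 4, size=spec.utr5)])
        utr3 = "".join(np.array(list(BASES))[rng.integers(0, 4, size=spec.utr3)])
        tid = f"t{i + 1:04d}"
        sequences[tid] = utr5 + orf + utr3
        orfs[tid] = (spec.utr5, spec.utr5 + len(orf))
    return Transcriptome(sequences=sequences, orfs=orfs)


def simulate_footprints(transcriptome: Transcriptome, dwell: DwellModel, spec: SimSpec,
                        sample_id: str, condition: str, seed: int) -> pd.DataFrame:
    """Simulate one sample's footprints under the stationary occupancy model.

    Each read: (i) pick an ORF sense codon beyond the first 5 codons with
    probability proportional to its (condition-adjusted) dwell weight,
    (ii) place the 5' end so the codon occupies read positions 15-17,
    (iii) draw the length from the 28-32 distribution keeping the 5' end
    fixed, (iv) with probability off_frame_fraction shift the 5' end by
    +/-1 nt.  Reads extending past transcript ends are redrawn.
    """
    rng = np.random.default_rng(seed)
    weight_by_codon = dict(zip(SENSE_CODONS, dwell.weight_vector(condition)))

    cand_tid: list[str] = []
    cand_start: list[np.ndarray] = []
    cand_weight: list[np.ndarray] = []
    tlen: dict[str, int] = {}
    for tid, seq in transcriptome.sequences.items():
        cds_start, cds_end = transcriptome.orfs[tid]
        tlen[tid] = len(seq)
        n_sense = (cds_end - cds_start) // 3 - 1
        if n_sense <= 5:
            # no codon beyond the first five: cannot host a footprint
            continue
        codon_idx = np.arange(5, n_sense)  # 0-based; skip the first 5 codons
        starts = cds_start + 3 * codon_idx
        codons = [seq[s : s + 3] for s in starts]
        weights = np.array([weight_by_codon.get(c, 0.0) for c in codons])
        keep = weights > 0
        cand_tid.append(tid)
        cand_start.append(starts[keep])
        cand_weight.append(weights[keep])
    if not cand_tid:
        raise ValueError("no transcript can host a footprint under this spec")

    flat_start = np.concatenate(cand_start)
    flat_tid = np.concatenate([np.full(len(s), i) for i, s in enumerate(cand_start)])
    flat_len = np.array([tlen[t] for t in cand_tid])
    probs = np.concatenate(cand_weight)
    probs = probs / probs.sum()

    lengths_supported = np.array(sorted(spec.read_length_probs))
    length_probs = np.array([spec.read_length_probs[l] for l in lengths_supported])

    n = spec.n_reads
    five_prime = np.empty(n, dtype=np.int64)
    t_index = np.empty(n, dtype=np.int64)
    read_len = np.empty(n, dtype=np.int64)
    todo = np.arange(n)
    while len(todo):
        pick = rng.choice(len(flat_start), size=len(todo), p=probs)
        fp = flat_start[pick] - 14
        ln = lengths_supported[rng.choice(len(lengths_supported), size=len(todo), p=length_probs)]
        shift = np.zeros(len(todo), dtype=np.int64)
        off = rng.random(len(todo)) < spec.off_frame_fraction
        shift[off] = rng.choice([-1, 1], size=int(off.sum()))
        fp = fp + shift
        ok = (fp >= 0) & (fp + ln <= flat_len[flat_tid[pick]])
        sel = todo[ok]
        five_prime[sel] = fp[ok]
        t_index[sel] = flat_tid[pick[ok]]
        read_len[sel] = ln[ok]
        todo = todo[~ok]

    tids = np.array(cand_tid)
    return pd.DataFrame({
        "read_id": [f"{sample_id}:{i}" for i in range(n)],
        "transcript_id": tids[t_index],
        "five_prime": five_prime,
        "length": read_len,
        "sample_id": sample_id,
        "condition": condition,
    })


def simulate_experiment(transcriptome: Transcriptome, dwell: DwellModel,
                        spec: SimSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All replicates of all conditions; returns (footprints, sample sheet)."""
    frames = []
    sheet = []
    offset = 0
    for condition, n_rep in spec.replicates.items():
        for rep in range(1, n_rep + 1):
            sample_id = f"{condition}{rep}"
            frames.append(simulate_footprints(
                transcriptome, dwell, spec, sample_id, condition, seed=spec.seed + 1000 + offset))
            sheet.append({"sample_id": sample_id, "condition": condition, "replicate": rep})
            offset += 1
    return pd.concat(frames, ignore_index=True), pd.DataFrame(sheet)


def simulate_chromatogram(sequence: str, fractions: tuple[float, float, float, float],
                          charge: int, noise_sd: float, seed: int,
                          rt_start: float = 4.0, rt_spacing: float = 0.5,
                          peak_sd_min: float = 0.05, rt_grid: np.ndarray | None = None,
                          ppm_jitter: float = 10.0, total_area: float = 1e6) -> pd.DataFrame:
    """Synthetic LC-MS trace of the four methyl species of one peptide.

    One Gaussian elution peak per methyl state, centred rt_spacing minutes
    apart (separated by default; co-elution is a parameter choice), peak area
    proportional to the state's fraction.  Each point's m/z is the state's
    theoretical m/z plus uniform ppm jitter within +/-(ppm_jitter/2); additive
    Gaussian baseline noise, floored at zero.  Columns: rt_min, mz, intensity.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    fr = np.asarray(fractions, dtype=float)
    if (fr < 0).any() or abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must be >= 0 and sum to 1")
    rng = np.random.default_rng(seed)
    if rt_grid is None:
        rt_grid = np.round(np.arange(rt_start - 1.0, rt_start + 3 * rt_spacing + 1.0, 0.005), 4)
    rows = []
    for state in range(4):
        theo = mz(MethylPeptideSpec(sequence, n_methyl=state, charge=charge))
        centre = rt_start + state * rt_spacing
        peak = fr[state] * total_area * np.exp(-0.5 * ((rt_grid - centre) / peak_sd_min) ** 2) \
            / (peak_sd_min * np.sqrt(2 * np.pi))
        noise = rng.normal(0.0, noise_sd, size=len(rt_grid)) if noise_sd else 0.0
        intensity = np.maximum(peak + noise, 0.0)
        jitter = rng.uniform(-ppm_jitter / 2, ppm_jitter / 2, size=len(rt_grid)) * 1e-6
        rows.append(pd.DataFrame({"rt_min": rt_grid, "mz": theo * (1 + jitter), "intensity": intensity}))
    return pd.concat(rows, ignore_index=True)


def xic_windows(sequence: str, charge: int, ppm: float) -> list[tuple[float, float]]:
    """The four Me0..Me3 extraction windows for a peptide at one charge."""
    return [ppm_window(mz(MethylPeptideSpec(sequence, n_methyl=n, charge=charge)), ppm)
            for n in range(4)]


def _matches_pattern(sequence: str, pattern: NTerminalPattern) -> bool:
    classes = pattern.classes
    if len(sequence) < len(classes):
        return False
    return all(sequence[i] in cls for i, cls in enumerate(classes))


def make_proteome_with_motifs(n_proteins: int, n_planted: int, pattern: NTerminalPattern,
                              seed: int, length: int = 40) -> dict[str, str]:
    """Random proteome with exactly n_planted N-terminal pattern matches.

    Planted sequences draw each constrained position uniformly from its
    class; every non-planted sequence is verified non-matching (resampled at
    the first constrained mismatch position if it accidentally matches).
    """
    if n_planted > n_proteins:
        raise ValueError(f"cannot plant {n_planted} motifs in {n_proteins} proteins")
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    proteome: dict[str, str] = {}
    planted_ids = set(rng.choice(n_proteins, size=n_planted, replace=False).tolist())
    for i in range(n_proteins):
        pid = f"P{i + 1:04d}"
        body = "".join(aa[rng.integers(0, len(aa), size=length)])
        if i in planted_ids:
            prefix = "".join(str(rng.choice(sorted(cls))) for cls in pattern.classes)
            seq = prefix + body[len(pattern.classes):]
        else:
            seq = "M" + body[1:]  # proteins start with iMet; rest random
            while _matches_pattern(seq, pattern):
                # break the match at the first mutable position
                pos = rng.integers(1, len(pattern.classes))
                forbidden = pattern.classes[pos]
                choices = [a for a in AMINO_ACIDS if a not in forbidden]
                seq = seq[:pos] + str(rng.choice(choices)) + seq[pos + 1:]
        proteome[pid] = seq
    return proteome


@dataclass
class MissingSpec:
    """Left-censoring rule: P(missing) rises linearly from 0 at ``threshold``
    (a quantile of the pooled intensities) down to ``max_prob`` at
    ``threshold - width`` log2 units below it."""

    threshold_quantile: float = 0.25
    width: float = 2.0
    max_prob: float = 0.8


def simulate_intensity_table(n_features: int, n_per_group: int,
                             effect_spec: list[tuple[list[int], float]] | None,
                             missing_spec: MissingSpec | None, seed: int,
                             baseline_mean: float = 25.0, baseline_sd: float = 2.0,
                             replicate_sd: float = 0.15,
                             group_names: tuple[str, str] = ("WT", "KO")) -> tuple[pd.DataFrame, pd.Series]:
    """Two-group log2 intensity table with planted effects and left-censoring.

    Intensities are log-normal: per-feature baseline ~ N(baseline_mean,
    baseline_sd^2) on the log2 scale, replicate noise sd ``replicate_sd``
    (defaults represent well-controlled isotope-label quantification).
    ``effect_spec`` lists (feature indices, log2 shift applied to group 2).
    Returns (table, truth) where truth marks the planted features.
    """
    if n_per_group < 2:
        raise ValueError("need at least 2 samples per group")
    rng = np.random.default_rng(seed)
    baselines = rng.normal(baseline_mean, baseline_sd, size=n_features)
    shifts = np.zeros(n_features)
    truth = np.zeros(n_features, dtype=bool)
    for indices, shift in (effect_spec or []):
        shifts[list(indices)] += shift
        truth[list(indices)] = True
    columns = [f"{group_names[0]}_{i + 1}" for i in range(n_per_group)] + \
              [f"{group_names[1]}_{i + 1}" for i in range(n_per_group)]
    data = np.empty((n_features, 2 * n_per_group))
    for j in range(n_per_group):
        data[:, j] = baselines + rng.normal(0, replicate_sd, size=n_features)
    for j in range(n_per_group):
        data[:, n_per_group + j] = baselines + shifts + rng.normal(0, replicate_sd, size=n_features)
    table = pd.DataFrame(data, columns=columns,
                         index=[f"f{i + 1:05d}" for i in range(n_features)])
    if missing_spec is not None:
        pooled = table.to_numpy().ravel()
        threshold = np.quantile(pooled, missing_spec.threshold_quantile)
        depth = np.clip((threshold - table.to_numpy()) / missing_spec.width, 0.0, 1.0)
        drop = rng.random(table.shape) < depth * missing_spec.max_prob
        table = table.mask(drop)
    return table, pd.Series(truth, index=table.index, name="planted")
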