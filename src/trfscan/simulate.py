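"""Synthetic data with the statistical structure of the lamb-skin study.

Every input the pipeline consumes can be generated here: a toy genome with
multi-copy tRNA genes on both strands, small-RNA read sets whose length
distribution mixes a uniform background, a canonical 22 nt miRNA peak and a
32 nt tRNA-fragment component whose abundance differs between groups by a
configured fold, a proteome table with planted group shifts, a metabolome
table with planted discriminators and pooled QC samples, qPCR Ct tables, a
3'UTR set with planted complementary target sites, and gene-set collections
for enrichment testing.

Ground truth (which entities carry planted effects) is emitted alongside the
data and must never feed the pipeline; truth files use the ``.truth.json``
suffix and stage loaders refuse them.

All generators are deterministic for a fixed ``SimConfig.seed``; independent
streams are derived per generator so adding samples to one table does not
perturb another.
"""

from __future__ import annotations

import math
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import TrnaLocus
from .config import GROUP_COARSE, GROUP_FINE, QC_ROLE, SimConfig
from .errors import ConfigError
from .sequtils import revcomp
from .spectrum import LengthSpectrum, ReadSet, spectrum_from_counts

TRUTH_SUFFIX = ".truth.json"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# per-generator RNG stream keys, so generators stay independent
_STREAM_GENOME = 0
_STREAM_READS = 1
_STREAM_PROTEOME = 2
_STREAM_METABOLOME = 3
_STREAM_QPCR = 4
_STREAM_UTRS = 5
_STREAM_GENESETS = 6


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def _random_seqs(rng: np.random.Generator, lengths: np.ndarray) -> list[str]:
    """Vectorised batch of random sequences with the given lengths."""
    if lengths.size == 0:
        return []
    mat = _BASES[rng.integers(0, 4, size=(lengths.size, int(lengths.max())))]
    return [mat[i, : lengths[i]].tobytes().decode("ascii")
            for i in range(lengths.size)]


# ---------------------------------------------------------------------------
# genome and tRNA loci
# ---------------------------------------------------------------------------

def generate_toy_genome(config: SimConfig,
                        ) -> tuple[dict[str, str], list[TrnaLocus]]:
    """A toy genome with ``trna_copies`` embedded tRNA gene copies.

    All copies share one random gene sequence of ``trna_gene_length`` nt;
    minus-strand loci carry its reverse complement on the forward reference.
    Intervals are 1-based fully closed.  Flanking sequence is random and
    rejection-checked so the 5' fragment of the gene occurs in the genome
    exactly once per copy (no accidental extra matches).
    """
    config.validate()
    rng = _rng(config, _STREAM_GENOME)
    n_chrom = max(1, min(config.n_chromosomes, config.trna_copies))
    n_ccc = math.ceil(config.trna_copies * 0.6)
    for _attempt in range(20):
        gene = _random_seq(rng, config.trna_gene_length)
        fragment = gene[: config.fragment_length]
        genome: dict[str, str] = {}
        loci: list[TrnaLocus] = []
        copy_idx = 0
        per_chrom = _split_round_robin(config.trna_copies, n_chrom)
        for c in range(n_chrom):
            parts: list[str] = []
            pos = 0  # 0-based length so far
            for _ in range(per_chrom[c]):
                flank = _random_seq(rng, int(rng.integers(300, 600)))
                parts.append(flank)
                pos += len(flank)
                strand = "+" if rng.random() < 0.5 else "-"
                name = "TRNAG-CCC" if copy_idx < n_ccc else "TRNAG-GCC"
                parts.append(gene if strand == "+" else revcomp(gene))
                start = pos + 1  # 1-based
                end = pos + config.trna_gene_length
                loci.append(TrnaLocus(f"chr{c + 1}", start, end, strand, name))
                pos = end
                copy_idx += 1
            parts.append(_random_seq(rng, int(rng.integers(300, 600))))
            genome[f"chr{c + 1}"] = "".join(parts)
        if _fragment_occurrences(genome, fragment) == config.trna_copies:
            return genome, loci
    raise RuntimeError("could not generate a genome free of accidental fragment copies")


def _split_round_robin(total: int, bins: int) -> list[int]:
    base, extra = divmod(total, bins)
    return [base + (1 if i < extra else 0) for i in range(bins)]


def _fragment_occurrences(genome: dict[str, str], fragment: str) -> int:
    rc = revcomp(fragment)
    n = 0
    for seq in genome.values():
        for probe in (fragment, rc):
            start = 0
            while True:
                i = seq.find(probe, start)
                if i == -1:
                    break
                n += 1
                start = i + 1
    return n


def fragment_sequence(genome: dict[str, str], loci: Sequence[TrnaLocus],
                      fragment_length: int) -> str:
    """The 5'-anchored fragment of the tRNA gene, from its first locus."""
    loc = loci[0]
    chrom = genome[loc.chrom]
    if loc.strand == "+":
        return chrom[loc.start - 1: loc.start - 1 + fragment_length]
    return revcomp(chrom[loc.end - fragment_length: loc.end])


def decoy_sequences(genome: dict[str, str], loci: Sequence[TrnaLocus],
                    config: SimConfig,
                    rng: Optional[np.random.Generator] = None) -> list[str]:
    """Non-tRNA 32nt sequences sharing the anomalous peak with the fragment.

    Drawn from genomic regions outside every locus so the annotator classes
    them ``unannotated`` (the negative path of locus intersection).
    """
    if rng is None:
        rng = _rng(config, _STREAM_READS)
    fragment = fragment_sequence(genome, loci, config.fragment_length)
    by_chrom: dict[str, list[TrnaLocus]] = {}
    for loc in loci:
        by_chrom.setdefault(loc.chrom, []).append(loc)
    chroms = sorted(genome)
    decoys: list[str] = []
    guard = 0
    while len(decoys) < config.n_decoys:
        guard += 1
        if guard > 10_000:
            raise RuntimeError("could not place decoy sequences outside loci")
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        seq = genome[chrom]
        if len(seq) < config.fragment_length:
            continue
        start = int(rng.integers(0, len(seq) - config.fragment_length + 1))
        end = start + config.fragment_length  # 0-based half-open
        if any(not (end <= loc.start - 1 or start >= loc.end)
               for loc in by_chrom.get(chrom, [])):
            continue
        cand = seq[start:end]
        if cand == fragment or cand in decoys:
            continue
        decoys.append(cand)
    return decoys


# ---------------------------------------------------------------------------
# small-RNA reads
# ---------------------------------------------------------------------------

def _group_weights(config: SimConfig, group: str) -> tuple[float, float, float]:
    """(background, miRNA, 32nt-fragment) component weights for a group.

    The miRNA weight is the same in both groups and the fragment weight is
    ``trf_weight_coarse`` in the coarse group and ``trf_weight_coarse /
    trf_fold`` in the fine group, so the expected group ratio of
    fragment-component counts equals ``trf_fold`` by construction.
    """
    p_trf = config.trf_weight_coarse
    if group == GROUP_FINE:
        p_trf /= config.trf_fold
    p_mir = config.mirna_weight
    return 1.0 - p_mir - p_trf, p_mir, p_trf


def mirna_panel(config: SimConfig, n: int = 5) -> list[str]:
    """Fixed panel of canonical-length miRNA sequences for the 22 nt peak."""
    rng = np.random.default_rng([int(config.seed), _STREAM_READS, 99])
    return [_random_seq(rng, config.mirna_peak_length) for _ in range(n)]


def simulate_small_rna_reads(genome: dict[str, str],
                             loci: Sequence[TrnaLocus],
                             config: SimConfig) -> list[ReadSet]:
    """Per-sample read sets from the three-component length mixture.

    Background reads are random sequences with lengths uniform over the
    retained window; the miRNA component draws from a fixed 22 nt panel; the
    fragment component emits the 5'-anchored tRNA fragment with the
    group-specific dominant fraction and splits the rest uniformly among the
    decoy sequences.
    """
    config.validate()
    if config.trf_weight_coarse > 0 and not loci:
        raise ConfigError("32nt component requested but locus list is empty")
    rng = _rng(config, _STREAM_READS)
    fragment = fragment_sequence(genome, loci, config.fragment_length) if loci else ""
    decoys = decoy_sequences(genome, loci, config, rng) if loci else []
    panel = mirna_panel(config)
    dom = {GROUP_COARSE: config.dominant_fraction_coarse,
           GROUP_FINE: config.dominant_fraction_fine}
    readsets: list[ReadSet] = []
    for group in (GROUP_COARSE, GROUP_FINE):
        p_bg, p_mir, p_trf = _group_weights(config, group)
        for i in range(config.n_per_group):
            n_bg, n_mir, n_trf = rng.multinomial(
                config.read_depth, [p_bg, p_mir, p_trf])
            reads: list[str] = []
            bg_lengths = rng.integers(config.min_len, config.max_len + 1,
                                      size=n_bg)
            reads.extend(_random_seqs(rng, bg_lengths))
            reads.extend(panel[j] for j in rng.integers(0, len(panel),
                                                        size=n_mir))
            n_dom = rng.binomial(n_trf, dom[group])
            reads.extend([fragment] * int(n_dom))
            n_rest = int(n_trf - n_dom)
            if n_rest and decoys:
                picks = rng.integers(0, len(decoys), size=n_rest)
                reads.extend(decoys[j] for j in picks)
            readsets.append(ReadSet(f"{group}_{i + 1}", group, reads))
    return readsets


def simulate_length_counts(config: SimConfig,
                           seed: Optional[int] = None) -> list[LengthSpectrum]:
    """Per-sample length tallies drawn from the read mixture's marginal.

    Identical in distribution to tallying ``simulate_small_rna_reads``
    output by length, without materialising sequences; used for
    calibration studies over many seeds.
    """
    config.validate()
    rng = np.random.default_rng(
        [int(config.seed if seed is None else seed), _STREAM_READS, 7])
    lengths = list(range(config.min_len, config.max_len + 1))
    n_len = len(lengths)
    idx_mir = lengths.index(config.mirna_peak_length)
    idx_trf = lengths.index(config.fragment_length)
    spectra: list[LengthSpectrum] = []
    for group in (GROUP_COARSE, GROUP_FINE):
        p_bg, p_mir, p_trf = _group_weights(config, group)
        probs = np.full(n_len, p_bg / n_len)
        probs[idx_mir] += p_mir
        probs[idx_trf] += p_trf
        for i in range(config.n_per_group):
            counts = rng.multinomial(config.read_depth, probs)
            spectra.append(spectrum_from_counts(
                f"{group}_{i + 1}", group, dict(zip(lengths, counts))))
    return spectra


# ---------------------------------------------------------------------------
# proteome / 3'UTRs / gene sets
# ---------------------------------------------------------------------------

def simulate_proteome(config: SimConfig,
                      ) -> tuple[pd.DataFrame, dict[str, str], dict]:
    """Protein abundance table (linear scale) with planted group shifts.

    Log2 abundances are Gaussian and homoscedastic; the first
    ``n_up_proteins`` are shifted up and the next ``n_down_proteins`` down
    in the coarse group.  A configured fraction of the down set plus some
    null proteins are flagged as planted fragment targets, exercising the
    target/DEP overlap stage.  Returns (table, column->group, truth).
    """
    config.validate()
    if config.n_per_group < 2:
        raise ConfigError("n_per_group must be >= 2 for the proteome t-test")
    rng = _rng(config, _STREAM_PROTEOME)
    n = config.protein_count
    ids = [f"P{i + 1:04d}" for i in range(n)]
    up = ids[: config.n_up_proteins]
    down = ids[config.n_up_proteins: config.n_up_proteins + config.n_down_proteins]
    base = rng.normal(7.0, 1.0, size=n)
    effect = np.zeros(n)
    effect[: config.n_up_proteins] = config.protein_effect_log2
    effect[config.n_up_proteins: config.n_up_proteins + config.n_down_proteins] = \
        -config.protein_effect_log2
    cols, data, groups = [], [], {}
    for group, shift in ((GROUP_COARSE, effect), (GROUP_FINE, 0.0)):
        for i in range(config.n_per_group):
            col = f"{group}_{i + 1}"
            noise = rng.normal(0.0, config.protein_noise_sd, size=n)
            data.append(2.0 ** (base + shift + noise))
            cols.append(col)
            groups[col] = group
    table = pd.DataFrame(np.column_stack(data), index=ids, columns=cols)
    n_target_down = math.ceil(config.target_fraction_of_down * len(down))
    null_ids = ids[config.n_up_proteins + config.n_down_proteins:]
    targets = down[:n_target_down] + null_ids[: config.n_extra_targets]
    truth = {"up": up, "down": down, "targets": targets}
    return table, groups, truth


def generate_utrs(config: SimConfig, protein_ids: Sequence[str],
                  target_ids: Iterable[str], fragment: str) -> dict[str, str]:
    """One 3'UTR per protein; planted targets carry a perfect site.

    The site is the reverse complement of the fragment, embedded at a random
    position, so the duplex scan pairs the fragment end-to-end.
    """
    rng = _rng(config, _STREAM_UTRS)
    targets = set(target_ids)
    utrs: dict[str, str] = {}
    site = revcomp(fragment)
    for pid in protein_ids:
        seq = _random_seq(rng, config.utr_length)
        if pid in targets:
            pos = int(rng.integers(0, config.utr_length - len(site) + 1))
            seq = seq[:pos] + site + seq[pos + len(site):]
        utrs[pid] = seq
    return utrs


def make_gene_sets(protein_ids: Sequence[str], truth: dict,
                   config: SimConfig) -> dict[str, set[str]]:
    """Small pathway collection for the over-representation stage.

    Three sets are built around the planted targets (mirroring metabolic /
    glutathione / ROS-style pathways); the rest are random draws from the
    protein universe.
    """
    rng = _rng(config, _STREAM_GENESETS)
    ids = list(protein_ids)
    targets = list(truth["targets"])
    sets: dict[str, set[str]] = {}
    extra = [i for i in ids if i not in set(targets)]
    sets["Metabolic"] = set(targets) | set(
        rng.choice(extra, size=min(40, len(extra)), replace=False))
    half = max(1, len(targets) // 2)
    sets["Glutathione"] = set(targets[:half])
    sets["ROS"] = set(targets[half:]) | set(
        rng.choice(extra, size=min(10, len(extra)), replace=False))
    for k in range(10):
        size = min(int(rng.integers(15, 60)), len(ids))
        sets[f"RandomSet{k + 1:02d}"] = set(
            rng.choice(ids, size=size, replace=False))
    return sets


# ---------------------------------------------------------------------------
# metabolome
# ---------------------------------------------------------------------------

def simulate_metabolome(config: SimConfig,
                        ) -> tuple[pd.DataFrame, dict[str, str], dict]:
    """Metabolite intensity table with planted discriminators and QC columns.

    Intensities are log-normal; the first ``n_discriminators`` metabolites
    carry a group shift of alternating sign.  The last
    ``n_sparse_metabolites`` are mostly zero in both groups (prevalence-
    filter fodder).  QC columns are the pooled mean profile of all group
    samples times small log-normal technical noise.  Returns
    (table, column->role, truth); roles are group labels or ``QC``.
    """
    config.validate()
    if config.n_per_group < 2:
        raise ConfigError("n_per_group must be >= 2 for the metabolome screen")
    rng = _rng(config, _STREAM_METABOLOME)
    n = config.metabolite_count
    ids = [f"M{i + 1:04d}" for i in range(n)]
    n_disc = config.n_discriminators
    n_sparse = min(config.n_sparse_metabolites, n - n_disc)
    base = rng.normal(17.0, 1.0, size=n)
    effect = np.zeros(n)
    signs = np.where(np.arange(n_disc) % 2 == 0, 1.0, -1.0)
    effect[:n_disc] = signs * config.metabolite_effect_log2
    sparse_idx = np.arange(n - n_sparse, n)
    cols, data, roles = [], [], {}
    for group, shift in ((GROUP_COARSE, effect), (GROUP_FINE, 0.0)):
        for i in range(config.n_per_group):
            col = f"{group}_{i + 1}"
            noise = rng.normal(0.0, config.metabolite_noise_sd, size=n)
            x = 2.0 ** (base + shift + noise)
            dropout = rng.random(size=n_sparse) > 0.3  # mostly zero
            x[sparse_idx] = np.where(dropout, 0.0, x[sparse_idx])
            data.append(x)
            cols.append(col)
            roles[col] = group
    profile = np.mean(np.column_stack(data), axis=1)  # pooled mean profile
    for i in range(config.n_qc):
        col = f"QC_{i + 1}"
        x = profile * 2.0 ** rng.normal(0.0, config.qc_noise_sd, size=n)
        data.append(x)
        cols.append(col)
        roles[col] = QC_ROLE
    table = pd.DataFrame(np.column_stack(data), index=ids, columns=cols)
    truth = {"discriminators": ids[:n_disc],
             "sparse": [ids[int(i)] for i in sparse_idx]}
    return table, roles, truth


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

def simulate_qpcr(config: SimConfig,
                  fold_coarse_over_fine: Optional[float] = None,
                  n_per_group: Optional[int] = None,
                  stream: int = _STREAM_QPCR) -> pd.DataFrame:
    """Ct table encoding a true coarse/fine expression fold.

    The reference-gene Ct is stable across groups; the target dCt of the
    coarse group is shifted by -log2(fold) relative to the fine group, so a
    ddCt analysis with the fine group as control recovers the fold.  Ct
    noise is Gaussian with sd ``qpcr_noise_sd``.
    """
    config.validate()
    fold = config.trf_fold if fold_coarse_over_fine is None else fold_coarse_over_fine
    if fold <= 0:
        raise ConfigError("true fold must be > 0")
    n = config.n_per_group if n_per_group is None else n_per_group
    rng = _rng(config, stream)
    rows = []
    base_dct = 6.0
    for group in (GROUP_COARSE, GROUP_FINE):
        dct = base_dct - (math.log2(fold) if group == GROUP_COARSE else 0.0)
        for i in range(n):
            ct_ref = 18.0 + rng.normal(0.0, config.qpcr_noise_sd)
            ct_tgt = ct_ref + dct + rng.normal(0.0, config.qpcr_noise_sd)
            rows.append({"sample": f"{group}_{i + 1}", "group": group,
                         "ct_target": ct_tgt, "ct_reference": ct_ref})
    return pd.DataFrame(rows)
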