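"""Synthetic references and two-condition small-RNA libraries with truth.

The generator emulates the statistical structure a small-RNA analysis
assumes: mature miRNAs of 20-24 nt (peak 21-23) with a ~50% 5'-U bias,
hairpin precursors embedding the mature in one arm with a near-reverse-
complement star arm, a genome carrying every precursor (and contaminant)
verbatim, contaminant ncRNA fragments, 3' sequencing adapters, isomiR
structure (3' trimming, templated extension, non-templated U/A addition,
internal substitutions drawn from a 12-type spectrum), seed edits
confined to configured positions within 2-8, and a configurable fraction
of low-quality reads.

Per-miRNA baseline abundances are log-normal (wide dynamic range);
library counts are multinomial given expected proportions, with condition
B proportions scaled by 2^(planted log2 fold-change); an optional
gamma-mixing knob adds negative-binomial-style overdispersion (default
off). Every simulated read is accounted for in the ground-truth table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._seq import RNA_BASES, revcomp_rna, to_dna
from .refs import Contaminant, MatureMiRNA, Precursor, ReferenceBundle

__all__ = [
    "DEFAULT_SPECTRUM",
    "DEFAULT_ADAPTER",
    "SimulationConfig",
    "generate_reference",
    "simulate_counts",
    "SimResult",
    "simulate_libraries",
]

#: 3' adapter: a fixed 12-nt constant suffix (configurable).
DEFAULT_ADAPTER = "TGGAATTCTCGG"

#: 12-type substitution spectrum; the four named rates follow the
#: empirically dominant types (G->U, U->C, G->A, A->G), the remaining
#: eight share the leftover mass equally.
DEFAULT_SPECTRUM: Dict[Tuple[str, str], float] = {
    ("G", "U"): 0.159,
    ("U", "C"): 0.121,
    ("G", "A"): 0.112,
    ("A", "G"): 0.112,
}
_rest = (1.0 - sum(DEFAULT_SPECTRUM.values())) / 8.0
for _a in RNA_BASES:
    for _b in RNA_BASES:
        if _a != _b and (_a, _b) not in DEFAULT_SPECTRUM:
            DEFAULT_SPECTRUM[(_a, _b)] = _rest

_MATURE_LENGTHS = np.array([20, 21, 22, 23, 24])
_MATURE_LENGTH_P = np.array([0.10, 0.25, 0.30, 0.25, 0.10])
_CONTAMINANT_CLASSES = ("rRNA", "tRNA", "snRNA", "snoRNA", "repeat")


@dataclass
class SimulationConfig:
    """Rates and shapes of the simulated libraries (the study conditions)."""

    adapter: str = DEFAULT_ADAPTER
    contaminant_fraction: float = 0.05
    polya_fraction: float = 0.01
    low_quality_fraction: float = 0.05
    trim3_rate: float = 0.12
    ext3_templated_rate: float = 0.04
    add3_rate: float = 0.08
    add3_u_prob: float = 0.6
    substitution_rate: float = 0.04
    seed_edit_rate: float = 0.0
    seed_edit_positions: Tuple[int, ...] = (5, 6, 7, 8)
    spectrum: Dict[Tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_SPECTRUM)
    )
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 1.5
    star_expression_ratio: float = 0.2
    star_expressed_fraction: float = 1.0
    dispersion: float = 0.0  # gamma-mixing overdispersion, 0 = pure multinomial
    good_quality: float = 35.0
    bad_quality: float = 12.0
    quality_sd: float = 2.0

    def validate(self) -> None:
        total = sum(self.spectrum.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"substitution spectrum sums to {total}, not 1")
        class_rate = (
            self.trim3_rate + self.ext3_templated_rate + self.add3_rate
            + self.substitution_rate + self.seed_edit_rate
        )
        if class_rate > 1.0:
            raise ValueError("variant-class rates exceed 1")
        if self.contaminant_fraction + self.polya_fraction >= 1.0:
            raise ValueError("contaminant and poly-A fractions exceed 1")
        for pos in self.seed_edit_positions:
            if not 2 <= pos <= 8:
                raise ValueError("seed-edit positions must lie within 2-8")


def _random_rna(rng: np.random.Generator, length: int, p=None) -> str:
    return "".join(rng.choice(list(RNA_BASES), size=length, p=p))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = rng.choice([b for b in RNA_BASES if b != out[i]])
    return "".join(out)


def generate_reference(
    n_mirnas: int,
    n_contaminants: int = 10,
    rng_seed: int = 0,
    n_transcripts: Optional[int] = None,
    five_prime_u_prob: float = 0.5,
    star_mutation_rate: float = 0.08,
    spacer_length: Tuple[int, int] = (150, 300),
) -> ReferenceBundle:
    """Build a self-consistent synthetic reference bundle.

    Every mature occurs verbatim in exactly one arm of its precursor,
    every precursor (and contaminant) occurs verbatim in the genome at a
    recorded 0-based half-open locus, and roughly ``five_prime_u_prob``
    of matures start with U. Deterministic given ``rng_seed``.
    """
    if n_mirnas < 1:
        raise ValueError("n_mirnas must be >= 1")
    if n_contaminants < 0:
        raise ValueError("n_contaminants must be >= 0")
    rng = np.random.default_rng(rng_seed)

    matures: List[MatureMiRNA] = []
    stars: List[MatureMiRNA] = []
    precursors: List[Precursor] = []
    seen = set()
    for i in range(n_mirnas):
        for _attempt in range(100):
            L = int(rng.choice(_MATURE_LENGTHS, p=_MATURE_LENGTH_P))
            first = "U" if rng.random() < five_prime_u_prob else rng.choice(list("ACG"))
            mature_seq = first + _random_rna(rng, L - 1)
            star_seq = _mutate(rng, revcomp_rna(mature_seq), star_mutation_rate)
            arm = "5p" if rng.random() < 0.5 else "3p"
            arm5, arm3 = (mature_seq, star_seq) if arm == "5p" else (star_seq, mature_seq)
            loop = _random_rna(rng, int(rng.integers(9, 13)),
                               p=[0.4, 0.4, 0.1, 0.1])
            flank5 = _random_rna(rng, int(rng.integers(5, 9)))
            flank3 = _random_rna(rng, int(rng.integers(5, 9)))
            seq = flank5 + arm5 + loop + arm3 + flank3
            if mature_seq in seen or star_seq in seen:
                continue
            if seq.count(mature_seq) != 1 or seq.count(star_seq) != 1:
                continue
            break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError("failed to generate a unique precursor")
        seen.add(mature_seq)
        seen.add(star_seq)
        base = f"mir-{i + 1}"
        prec_id = f"pre-{base}"
        a5 = (len(flank5), len(flank5) + len(arm5))
        a3 = (a5[1] + len(loop), a5[1] + len(loop) + len(arm3))
        precursors.append(Precursor(prec_id, seq, a5, a3, arm))
        star_arm = "3p" if arm == "5p" else "5p"
        matures.append(MatureMiRNA(f"{base}-{arm}", mature_seq, prec_id, arm))
        stars.append(MatureMiRNA(f"{base}-{star_arm}", star_seq, prec_id, star_arm))

    contaminants = [
        Contaminant(
            f"{_CONTAMINANT_CLASSES[j % len(_CONTAMINANT_CLASSES)]}-{j + 1}",
            _CONTAMINANT_CLASSES[j % len(_CONTAMINANT_CLASSES)],
            _random_rna(rng, int(rng.integers(60, 151))),
        )
        for j in range(n_contaminants)
    ]

    # genome: random spacers with precursors and contaminants inserted at
    # recorded forward-strand coordinates
    parts: List[str] = []
    precursor_loci, contaminant_loci = [], []
    pos = 0
    for prec in precursors:
        spacer = _random_rna(rng, int(rng.integers(*spacer_length)))
        parts.append(to_dna(spacer))
        pos += len(spacer)
        dna = to_dna(prec.sequence)
        parts.append(dna)
        precursor_loci.append((prec.precursor_id, "chr1", pos, pos + len(dna)))
        pos += len(dna)
    for cont in contaminants:
        spacer = _random_rna(rng, int(rng.integers(*spacer_length)))
        parts.append(to_dna(spacer))
        pos += len(spacer)
        dna = to_dna(cont.sequence)
        parts.append(dna)
        contaminant_loci.append(
            (cont.contaminant_id, "chr1", pos, pos + len(dna))
        )
        pos += len(dna)
    parts.append(to_dna(_random_rna(rng, int(rng.integers(*spacer_length)))))
    genome = {"chr1": "".join(parts)}

    if n_transcripts is None:
        n_transcripts = min(10, n_mirnas)
    transcripts, target_truth = [], []
    for t in range(n_transcripts):
        mat = matures[int(rng.integers(0, n_mirnas))]
        body = _random_rna(rng, int(rng.integers(400, 801)))
        site = revcomp_rna(mat.sequence)
        ins = int(rng.integers(50, len(body) - 50))
        seq = body[:ins] + site + body[ins:]
        tid = f"transcript-{t + 1}"
        transcripts.append((tid, seq))
        target_truth.append((tid, mat.mature_id, ins, ins + len(site)))

    return ReferenceBundle(
        mature_set=matures,
        star_set=stars,
        precursor_set=precursors,
        contaminant_set=contaminants,
        genome=genome,
        precursor_loci=precursor_loci,
        contaminant_loci=contaminant_loci,
        transcript_set=transcripts,
        target_truth=target_truth,
    )


def simulate_counts(
    baselines: np.ndarray,
    depth: int,
    log2fc: Optional[np.ndarray] = None,
    rng: Optional[np.random.Generator] = None,
    dispersion: float = 0.0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Two-library multinomial count vectors from baseline abundances.

    Condition-B expected abundance of item i is baseline_i * 2^log2fc_i.
    ``dispersion`` > 0 gamma-perturbs per-library weights (NB-style).
    """
    rng = rng or np.random.default_rng()
    baselines = np.asarray(baselines, dtype=float)
    lfc = np.zeros_like(baselines) if log2fc is None else np.asarray(log2fc, float)
    wa = baselines.copy()
    wb = baselines * np.exp2(lfc)
    if dispersion > 0:
        shape = 1.0 / dispersion
        wa = wa * rng.gamma(shape, dispersion, size=wa.shape)
        wb = wb * rng.gamma(shape, dispersion, size=wb.shape)
    x = rng.multinomial(depth, wa / wa.sum())
    y = rng.multinomial(depth, wb / wb.sum())
    return x, y


@dataclass
class SimResult:
    reads_a: List[Tuple[str, str, str]]  # (id, DNA sequence, phred+33 qual)
    reads_b: List[Tuple[str, str, str]]
    truth: pd.DataFrame  # library, origin_id, variant_class, count
    seed_edit_events: pd.DataFrame  # mature_id, position, ref, obs, count
    substitution_events: pd.DataFrame  # ref, obs, count (internal substitutions)
    baselines: Dict[str, float]
    log2fc: Dict[str, float]
    bundle: ReferenceBundle
    config: SimulationConfig

    def write(self, outdir: str) -> None:
        import os

        from .io import write_fasta, write_fastq

        os.makedirs(outdir, exist_ok=True)
        write_fastq(os.path.join(outdir, "library_a.fastq"), self.reads_a)
        write_fastq(os.path.join(outdir, "library_b.fastq"), self.reads_b)
        write_fasta(
            os.path.join(outdir, "mature.fasta"),
            [(m.mature_id, m.sequence) for m in self.bundle.all_products()],
        )
        write_fasta(
            os.path.join(outdir, "precursors.fasta"),
            [(p.precursor_id, p.sequence) for p in self.bundle.precursor_set],
        )
        write_fasta(
            os.path.join(outdir, "contaminants.fasta"),
            [
                (f"{c.contaminant_id}|{c.ncrna_class}", c.sequence)
                for c in self.bundle.contaminant_set
            ],
        )
        write_fasta(os.path.join(outdir, "genome.fasta"), self.bundle.genome.items())
        write_fasta(os.path.join(outdir, "transcripts.fasta"), self.bundle.transcript_set)
        self.truth.to_csv(os.path.join(outdir, "truth.tsv"), sep="\t", index=False)
        self.seed_edit_events.to_csv(
            os.path.join(outdir, "seed_edits.tsv"), sep="\t", index=False
        )


def _quality_string(rng: np.random.Generator, length: int, mean: float, sd: float) -> str:
    q = np.clip(np.rint(rng.normal(mean, sd, size=length)), 2, 40).astype(int)
    return "".join(chr(v + 33) for v in q)


def _apply_substitution(
    rng: np.random.Generator,
    seq: str,
    spectrum: Dict[Tuple[str, str], float],
    min_pos: int = 9,
) -> Optional[Tuple[str, int, str, str]]:
    """Plant one internal substitution drawn from the spectrum.

    Returns (new sequence, 1-based position, ref, obs) or None when no
    eligible position carries the drawn source base.
    """
    types = list(spectrum)
    probs = np.array([spectrum[t] for t in types])
    probs = probs / probs.sum()
    for _ in range(20):
        src, dst = types[rng.choice(len(types), p=probs)]
        positions = [
            i for i in range(min_pos - 1, len(seq)) if seq[i] == src
        ]
        if positions:
            i = int(rng.choice(positions))
            return seq[:i] + dst + seq[i + 1 :], i + 1, src, dst
    return None


def simulate_libraries(
    bundle: ReferenceBundle,
    config: Optional[SimulationConfig] = None,
    depth: int = 100_000,
    rng_seed: int = 0,
    log2fc: Optional[Dict[str, float]] = None,
) -> SimResult:
    """Simulate two small-RNA FASTQ libraries with full provenance.

    Condition B's expected count of miRNA i is baseline_i * 2^log2fc_i
    before multinomial sampling. Reads carry the 3' adapter as a suffix;
    isomiR and seed-edit reads are generated at the configured rates;
    a configured fraction of reads receives qualities failing the
    default quality floor. The truth table accounts for every read.
    """
    config = config or SimulationConfig()
    config.validate()
    if depth < 1000:
        raise ValueError("depth must be >= 1000")
    rng = np.random.default_rng(rng_seed)
    log2fc = dict(log2fc or {})

    products = bundle.all_products()
    n_prec = len(bundle.precursor_set)
    n_star_expr = int(round(config.star_expressed_fraction * n_prec))
    star_expressed = set(
        rng.choice(
            [p.precursor_id for p in bundle.precursor_set],
            size=n_star_expr,
            replace=False,
        )
    )
    baselines: Dict[str, float] = {}
    for mat in bundle.mature_set:
        baselines[mat.mature_id] = float(
            rng.lognormal(config.lognormal_mu, config.lognormal_sigma)
        )
    for star in bundle.star_set:
        if star.precursor_id in star_expressed:
            guide = next(
                m for m in bundle.mature_set if m.precursor_id == star.precursor_id
            )
            baselines[star.mature_id] = (
                baselines[guide.mature_id] * config.star_expression_ratio
            )

    expressed = [p for p in products if p.mature_id in baselines]
    origin_ids = [p.mature_id for p in expressed]
    origin_seqs = {p.mature_id: p.sequence for p in expressed}
    prec_by_id = {p.precursor_id: p for p in bundle.precursor_set}
    prec_of = {p.mature_id: p.precursor_id for p in expressed}

    mirna_mass = 1.0 - config.contaminant_fraction - config.polya_fraction
    base_w = np.array([baselines[i] for i in origin_ids])
    categories = list(origin_ids)
    w_a = list(mirna_mass * base_w / base_w.sum())
    lfc_vec = np.array([log2fc.get(i, 0.0) for i in origin_ids])
    wb_mirna = base_w * np.exp2(lfc_vec)
    w_b = list(mirna_mass * wb_mirna / wb_mirna.sum())
    if bundle.contaminant_set and config.contaminant_fraction > 0:
        share = config.contaminant_fraction / len(bundle.contaminant_set)
        for cont in bundle.contaminant_set:
            categories.append(cont.contaminant_id)
            w_a.append(share)
            w_b.append(share)
    elif config.contaminant_fraction > 0:
        # no contaminant references: fold the mass back into miRNAs
        w_a = [w * (1.0 + config.contaminant_fraction / mirna_mass) for w in w_a]
        w_b = [w * (1.0 + config.contaminant_fraction / mirna_mass) for w in w_b]
    if config.polya_fraction > 0:
        categories.append("polyA_junk")
        w_a.append(config.polya_fraction)
        w_b.append(config.polya_fraction)

    contaminant_by_id = {c.contaminant_id: c for c in bundle.contaminant_set}
    class_probs = np.array(
        [
            config.trim3_rate,
            config.ext3_templated_rate,
            config.add3_rate,
            config.substitution_rate,
            config.seed_edit_rate,
        ]
    )
    class_probs = np.append(1.0 - class_probs.sum(), class_probs)
    class_names = [
        "canonical", "trim3", "ext3_templated", "add3_nontemplated",
        "substitution", "seed_edit",
    ]

    truth_rows: List[Tuple[str, str, str, int]] = []
    seed_edit_counter: Dict[Tuple[str, int, str, str], int] = {}
    substitution_counter: Dict[Tuple[str, str], int] = {}

    def make_read(origin: str, variant: str) -> str:
        seq = origin_seqs.get(origin)
        if origin == "polyA_junk":
            return "A" * int(rng.integers(20, 25))
        if origin in contaminant_by_id:
            ref = contaminant_by_id[origin].sequence
            L = int(rng.integers(18, min(27, len(ref) + 1)))
            start = int(rng.integers(0, len(ref) - L + 1))
            return ref[start : start + L]
        if variant == "trim3":
            k = int(rng.integers(1, 3))
            return seq[:-k]
        if variant == "ext3_templated":
            prec = prec_by_id[prec_of[origin]]
            m_start = prec.sequence.find(seq)
            k = int(rng.integers(1, 3))
            ext = prec.sequence[m_start + len(seq) : m_start + len(seq) + k]
            return seq + ext if ext else seq
        if variant == "add3_nontemplated":
            prec = prec_by_id[prec_of[origin]]
            m_start = prec.sequence.find(seq)
            downstream = prec.sequence[m_start + len(seq) : m_start + len(seq) + 1]
            base = "U" if rng.random() < config.add3_u_prob else "A"
            if downstream == base:  # must be genuinely non-templated
                base = "A" if base == "U" else "U"
            return seq + base
        if variant == "substitution":
            planted = _apply_substitution(rng, seq, config.spectrum)
            if planted is None:
                return seq
            key = (planted[2], planted[3])
            substitution_counter[key] = substitution_counter.get(key, 0) + 1
            return planted[0]
        if variant == "seed_edit":
            pos = int(rng.choice(config.seed_edit_positions))
            ref_base = seq[pos - 1]
            obs = rng.choice([b for b in RNA_BASES if b != ref_base])
            key = (origin, pos, ref_base, str(obs))
            seed_edit_counter[key] = seed_edit_counter.get(key, 0) + 1
            return seq[: pos - 1] + obs + seq[pos:]
        return seq

    libraries = []
    for lib_name, weights in (("A", w_a), ("B", w_b)):
        w = np.asarray(weights, dtype=float)
        if config.dispersion > 0:
            shape = 1.0 / config.dispersion
            w = w * rng.gamma(shape, config.dispersion, size=w.shape)
        counts = rng.multinomial(depth, w / w.sum())
        reads: List[Tuple[str, str, str]] = []
        read_no = 0
        for cat, n in zip(categories, counts):
            if n == 0:
                continue
            if cat in origin_seqs:
                per_class = rng.multinomial(n, class_probs)
            else:
                per_class = None
                label = "junk" if cat == "polyA_junk" else "contaminant"
                truth_rows.append((lib_name, cat, label, int(n)))
            if per_class is not None:
                for cls_name, cls_n in zip(class_names, per_class):
                    if cls_n:
                        truth_rows.append((lib_name, cat, cls_name, int(cls_n)))
                class_iter = [
                    cls for cls, cn in zip(class_names, per_class) for _ in range(cn)
                ]
            else:
                class_iter = [None] * n
            for cls in class_iter:
                insert = make_read(cat, cls)
                dna = to_dna(insert) + config.adapter
                low_q = rng.random() < config.low_quality_fraction
                mean_q = config.bad_quality if low_q else config.good_quality
                qual = _quality_string(rng, len(dna), mean_q, config.quality_sd)
                reads.append((f"{lib_name}_{read_no}", dna, qual))
                read_no += 1
        libraries.append(reads)

    truth = pd.DataFrame(
        truth_rows, columns=["library", "origin_id", "variant_class", "count"]
    )
    seed_edits = pd.DataFrame(
        [(m, p, r, o, c) for (m, p, r, o), c in sorted(seed_edit_counter.items())],
        columns=["mature_id", "position", "ref", "obs", "count"],
    )
    substitutions = pd.DataFrame(
        [(r, o, c) for (r, o), c in sorted(substitution_counter.items())],
        columns=["ref", "obs", "count"],
    )
    return SimResult(
        reads_a=libraries[0],
        reads_b=libraries[1],
        truth=truth,
        seed_edit_events=seed_edits,
        substitution_events=substitutions,
        baselines=baselines,
        log2fc={i: log2fc.get(i, 0.0) for i in origin_ids},
        bundle=bundle,
        config=config,
    )
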