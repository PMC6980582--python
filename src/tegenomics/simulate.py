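"""Synthetic genomes, annotations, repeat families, expression and vote
tables with planted, machine-checkable ground truth.

All randomness flows from ``numpy.random.default_rng`` generators seeded
as ``[seed, component_offset]`` so that a single component can be
regenerated reproducibly. Identical configs produce byte-identical output
files.

Planted structure:

* exactly ``round(frac_te_surrounded * n_genes)`` genes get a qualifying
  (> 400 bp) repeat at ``flank_gap`` bp on BOTH flanks; every other gene
  gets at most one qualifying flank (rotating decoys: a left-only
  qualifying repeat, too-short repeats on both flanks, or nothing);
* TE-surrounded genes are silenced with ``p_silent_given_te``, others with
  ``p_silent_background``; non-silent genes are guaranteed expressed;
* repeat-family copies receive C→T (and reverse-strand G→A) mutations at
  ``rip_context`` sites plus background transversions, with exact per-copy
  bookkeeping;
* planted secreted/SSP/CAZyme genes get vote patterns that the voting
  rules recover exactly at zero noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import write_fasta, write_gff3, write_repeats_bed, write_table
from .models import ConfigError, GeneModel, GenomicInterval, RepeatHit, SequenceRecord
from .rip import CONTEXTS, MutationCounts, RepeatFamilyAlignment
from .voting import CAZYME_TOOLS, SECRETION_TOOLS

_BASES = np.array(list("ACGT"))
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_TRANSVERSIONS = {"A": "CT", "C": "AG", "G": "CT", "T": "AG"}

# component offsets for child RNGs
_RNG_GENOME, _RNG_EXPRESSION, _RNG_VOTES, _RNG_FAMILY = 0, 1, 2, 3

# spacing beyond the flank window so planted repeats of one gene can never
# qualify a neighboring gene
_WINDOW_PAD = 1100
_QUALIFYING_MIN_LEN = 400


@dataclass
class SimulationConfig:
    seed: int = 0
    n_scaffolds: int = 5
    scaffold_length: int = 1_000_000
    n_genes: int = 500
    gene_length: int = 1500
    frac_te_surrounded: float = 0.2
    te_length_range: tuple[int, int] = (500, 900)
    flank_gap: int = 200
    p_silent_given_te: float = 0.832
    p_silent_background: float = 0.3
    fpkm_log_mean: float = 1.5
    fpkm_log_sd: float = 1.0
    n_families: int = 20
    copies_per_family: int = 6
    family_length: int = 600
    rip_rate: float = 0.15
    rip_context: str = "CpG"
    background_transversion_rate: float = 0.005
    gc_content: float | None = None
    n_secreted: int = 40
    n_ssp: int = 25
    n_excluded_decoys: int = 8
    n_cazyme: int = 30
    expression_threshold: float = 1.0

    def __post_init__(self):
        probs = {
            "frac_te_surrounded": self.frac_te_surrounded,
            "p_silent_given_te": self.p_silent_given_te,
            "p_silent_background": self.p_silent_background,
            "rip_rate": self.rip_rate,
            "background_transversion_rate": self.background_transversion_rate,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {p}")
        lo, hi = self.te_length_range
        if lo <= 0 or hi < lo:
            raise ConfigError(f"invalid te_length_range {self.te_length_range}")
        if self.frac_te_surrounded > 0 and lo <= _QUALIFYING_MIN_LEN:
            raise ConfigError(
                f"te_length_range min must exceed {_QUALIFYING_MIN_LEN} bp "
                "for planted repeats to qualify"
            )
        if self.rip_context not in CONTEXTS:
            raise ConfigError(f"rip_context must be one of {CONTEXTS}")
        if self.gc_content is not None and not 0.0 < self.gc_content < 1.0:
            raise ConfigError("gc_content must be in (0, 1)")
        if self.n_ssp > self.n_secreted:
            raise ConfigError("n_ssp cannot exceed n_secreted")
        if self.n_genes > 0 and self.gene_length <= 0:
            raise ConfigError("gene_length must be positive")

    def rng(self, *offsets: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, *offsets])


@dataclass
class GroundTruth:
    te_surrounded_ids: set[str] = field(default_factory=set)
    silent_ids: set[str] = field(default_factory=set)
    rip_family_ids: set[str] = field(default_factory=set)
    rip_context: str = "CpG"
    secreted_ids: set[str] = field(default_factory=set)
    ssp_ids: set[str] = field(default_factory=set)
    cysteine_rich_ids: set[str] = field(default_factory=set)
    excluded_ids: set[str] = field(default_factory=set)
    cazyme_assignments: dict[str, list[str]] = field(default_factory=dict)
    planted_mutations: dict[str, list[dict]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "te_surrounded_ids": sorted(self.te_surrounded_ids),
            "silent_ids": sorted(self.silent_ids),
            "rip_family_ids": sorted(self.rip_family_ids),
            "rip_context": self.rip_context,
            "secreted_ids": sorted(self.secreted_ids),
            "ssp_ids": sorted(self.ssp_ids),
            "cysteine_rich_ids": sorted(self.cysteine_rich_ids),
            "excluded_ids": sorted(self.excluded_ids),
            "cazyme_assignments": {
                g: sorted(v) for g, v in sorted(self.cazyme_assignments.items())
            },
            "planted_mutations": self.planted_mutations,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            te_surrounded_ids=set(doc["te_surrounded_ids"]),
            silent_ids=set(doc["silent_ids"]),
            rip_family_ids=set(doc["rip_family_ids"]),
            rip_context=doc["rip_context"],
            secreted_ids=set(doc["secreted_ids"]),
            ssp_ids=set(doc["ssp_ids"]),
            cysteine_rich_ids=set(doc["cysteine_rich_ids"]),
            excluded_ids=set(doc["excluded_ids"]),
            cazyme_assignments={g: list(v) for g, v in doc["cazyme_assignments"].items()},
            planted_mutations=doc["planted_mutations"],
        )


@dataclass
class SimulatedGenome:
    sequences: list[SequenceRecord]
    genes: list[GeneModel]
    repeats: list[RepeatHit]
    truth: GroundTruth


_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_sequence(rng: np.random.Generator, length: int, gc: float | None) -> str:
    if gc is None:
        idx = rng.integers(0, 4, size=length)
    else:
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        idx = rng.choice(4, size=length, p=p)
    return _BASE_BYTES[idx].tobytes().decode("ascii")


def simulate_genome(config: SimulationConfig) -> SimulatedGenome:
    """Multi-scaffold genome with genes planted at controlled distances
    from repeats. See module docstring for the planted structure."""
    cfg = config
    rng = cfg.rng(_RNG_GENOME)
    te_min, te_max = cfg.te_length_range
    margin = cfg.flank_gap + te_max + _WINDOW_PAD
    slot = cfg.gene_length + 2 * margin
    n_per = -(-cfg.n_genes // cfg.n_scaffolds)  # ceil
    if n_per * slot > cfg.scaffold_length:
        raise ConfigError(
            f"cannot fit {n_per} gene slots of {slot} bp on a "
            f"{cfg.scaffold_length} bp scaffold"
        )
    if cfg.frac_te_surrounded > 0 and cfg.flank_gap >= 1000:
        raise ConfigError(
            "flank_gap must be below the 1000 bp detection window for "
            "planted repeats to qualify"
        )

    n_te = round(cfg.frac_te_surrounded * cfg.n_genes)
    te_idx = set(rng.choice(cfg.n_genes, size=n_te, replace=False).tolist())

    sequences, genes, repeats = [], [], []
    truth = GroundTruth(rip_context=cfg.rip_context)
    fam_classes = ("LTR/Gypsy", "LTR/Copia", "DNA/TcMar")

    gene_index = 0
    for s in range(cfg.n_scaffolds):
        name = f"scaffold_{s + 1:03d}"
        sequences.append(SequenceRecord(name, _random_sequence(rng, cfg.scaffold_length, cfg.gc_content)))
        for j in range(n_per):
            if gene_index >= cfg.n_genes:
                break
            gid = f"gene_{gene_index + 1:05d}"
            gstart = j * slot + margin
            gend = gstart + cfg.gene_length
            iv = GenomicInterval(name, gstart, gend, "+")
            genes.append(GeneModel(gid, iv, exons=[iv], cds=[iv]))

            def plant(side: str, length: int) -> None:
                fam = f"TE_fam_{int(rng.integers(0, 50)):02d}"
                cls = fam_classes[int(rng.integers(0, len(fam_classes)))]
                if side == "left":
                    end = gstart - cfg.flank_gap
                    riv = GenomicInterval(name, end - length, end, "+")
                else:
                    start = gend + cfg.flank_gap
                    riv = GenomicInterval(name, start, start + length, "+")
                repeats.append(RepeatHit(riv, fam, cls))

            if gene_index in te_idx:
                truth.te_surrounded_ids.add(gid)
                plant("left", int(rng.integers(te_min, te_max + 1)))
                plant("right", int(rng.integers(te_min, te_max + 1)))
            else:
                decoy = gene_index % 3
                if decoy == 0:  # one qualifying flank only
                    plant("left", int(rng.integers(te_min, te_max + 1)))
                elif decoy == 1:  # both flanks, but exactly at the length cutoff
                    plant("left", _QUALIFYING_MIN_LEN)
                    plant("right", _QUALIFYING_MIN_LEN)
            gene_index += 1
    return SimulatedGenome(sequences, genes, repeats, truth)


def simulate_expression(
    genes: list[GeneModel], truth: GroundTruth, config: SimulationConfig
) -> pd.DataFrame:
    """Three-stage FPKM table; silent genes are all-zero, non-silent genes
    are guaranteed > threshold in at least one stage. Updates
    ``truth.silent_ids``."""
    cfg = config
    rng = cfg.rng(_RNG_EXPRESSION)
    thr = cfg.expression_threshold
    rows = []
    for g in genes:
        p_silent = (
            cfg.p_silent_given_te
            if g.gene_id in truth.te_surrounded_ids
            else cfg.p_silent_background
        )
        if rng.random() < p_silent:
            truth.silent_ids.add(g.gene_id)
            vals = np.zeros(3)
        else:
            vals = rng.lognormal(cfg.fpkm_log_mean, cfg.fpkm_log_sd, size=3)
            for _ in range(200):
                if vals.max() > thr + 0.05:
                    break
                vals = rng.lognormal(cfg.fpkm_log_mean, cfg.fpkm_log_sd, size=3)
            else:
                vals = vals * (2.0 * (thr + 0.05) / vals.max())
        rows.append(
            {
                "gene_id": g.gene_id,
                "hyphae": round(float(vals[0]), 3),
                "primordia": round(float(vals[1]), 3),
                "fruiting_body": round(float(vals[2]), 3),
            }
        )
    return pd.DataFrame(rows)


def simulate_rip_family(
    config: SimulationConfig, family_id: str, family_index: int = 0
) -> tuple[RepeatFamilyAlignment, list[MutationCounts]]:
    """One gap-free repeat-family alignment with planted mutations.

    C sites whose 3' neighbor matches ``rip_context`` (and their
    reverse-strand G images) mutate to T (A) with ``rip_rate``; untouched
    sites receive transversions at ``background_transversion_rate``.
    Returns the alignment plus exact per-copy planted counts.
    """
    cfg = config
    rng = cfg.rng(_RNG_FAMILY, family_index)
    model = _random_sequence(rng, cfg.family_length, cfg.gc_content)
    ctx_base = cfg.rip_context[-1]  # the X of CpX
    rc_prev = _COMPLEMENT[ctx_base]

    copies, planted = [], []
    for _ in range(cfg.copies_per_family):
        seq = list(model)
        contexts = {c: 0 for c in CONTEXTS}
        ti = tv = 0
        mutated = set()
        for i, base in enumerate(model):
            if base == "C" and i + 1 < len(model) and model[i + 1] == ctx_base:
                if rng.random() < cfg.rip_rate:
                    seq[i] = "T"
                    contexts[cfg.rip_context] += 1
                    ti += 1
                    mutated.add(i)
            elif base == "G" and i > 0 and model[i - 1] == rc_prev:
                if rng.random() < cfg.rip_rate:
                    seq[i] = "A"
                    contexts[cfg.rip_context] += 1
                    ti += 1
                    mutated.add(i)
        for i, base in enumerate(model):
            if i in mutated:
                continue
            if rng.random() < cfg.background_transversion_rate:
                choices = _TRANSVERSIONS[base]
                seq[i] = choices[int(rng.integers(0, 2))]
                tv += 1
        copies.append("".join(seq))
        planted.append(MutationCounts(ti, tv, contexts))
    aln = RepeatFamilyAlignment(family_id, model, copies)
    return aln, planted


def simulate_families(
    config: SimulationConfig, truth: GroundTruth | None = None
) -> list[tuple[RepeatFamilyAlignment, list[MutationCounts]]]:
    out = []
    for k in range(config.n_families):
        fam_id = f"family_{k + 1:03d}"
        aln, planted = simulate_rip_family(config, fam_id, family_index=k)
        out.append((aln, planted))
        if truth is not None:
            truth.rip_family_ids.add(fam_id)
            truth.planted_mutations[fam_id] = [
                {
                    "transitions": m.transitions,
                    "transversions": m.transversions,
                    "contexts": dict(m.c_to_t_by_context),
                }
                for m in planted
            ]
    return out


_EXCLUSION_REASONS = ("tm_late", "tm_multi", "er", "gpi")


def simulate_votes(
    genes: list[GeneModel], truth: GroundTruth, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(secretion vote table, CAZyme vote table) with planted labels.

    Planted secreted genes carry >= 3 Y votes and survive the exclusion
    cascade; exclusion decoys carry >= 3 Y votes but fail exactly one
    exclusion; all other genes get <= 2 Y votes. Planted CAZyme families
    are supported by >= 2 agreeing predictors, decoys by at most one.
    Updates secreted/ssp/cysteine-rich/excluded/cazyme truth fields.
    """
    cfg = config
    rng = cfg.rng(_RNG_VOTES)
    gene_ids = [g.gene_id for g in genes]
    n_special = cfg.n_secreted + cfg.n_excluded_decoys
    if n_special > len(gene_ids):
        raise ConfigError("n_secreted + n_excluded_decoys exceeds n_genes")
    special = rng.choice(len(gene_ids), size=n_special, replace=False)
    secreted = [gene_ids[i] for i in special[: cfg.n_secreted]]
    excluded = [gene_ids[i] for i in special[cfg.n_secreted :]]
    truth.secreted_ids = set(secreted)
    truth.excluded_ids = set(excluded)
    ssp_set = set(secreted[: cfg.n_ssp])
    n_cys_rich = cfg.n_ssp // 2
    cys_rich_set = set(secreted[:n_cys_rich])

    rows = []
    for gid in gene_ids:
        is_secreted = gid in truth.secreted_ids
        is_excluded = gid in truth.excluded_ids
        if is_secreted or is_excluded:
            n_yes = 3 + int(rng.integers(0, 2))
        else:
            n_yes = int(rng.integers(0, 3))
        yes_tools = set(rng.choice(len(SECRETION_TOOLS), size=n_yes, replace=False).tolist())

        tm, er, gpi = "", "N", "N"
        if is_secreted:
            if gid in ssp_set:
                length = int(rng.integers(50, 300))
            else:
                length = int(rng.integers(301, 801))
            if rng.random() < 0.3:  # exempt single N-terminal helix
                start = int(rng.integers(1, 51))
                tm = f"{start}-{start + 20}"
        elif is_excluded:
            length = int(rng.integers(100, 801))
            reason = _EXCLUSION_REASONS[excluded.index(gid) % len(_EXCLUSION_REASONS)]
            if reason == "tm_late":
                start = int(rng.integers(100, 200))
                tm = f"{start}-{start + 20}"
            elif reason == "tm_multi":
                tm = "20-40;200-220"
            elif reason == "er":
                er = "Y"
            else:
                gpi = "Y"
        else:
            length = int(rng.integers(100, 1001))

        if gid in cys_rich_set:
            cys = int(length * 0.03) + 1 + int(rng.integers(0, 3))
        elif gid in ssp_set:
            cys = int(rng.integers(0, max(1, int(length * 0.03))))
        else:
            cys = int(rng.binomial(length, 0.015))
        rows.append(
            {
                "gene_id": gid,
                **{
                    tool: ("Y" if k in yes_tools else "N")
                    for k, tool in enumerate(SECRETION_TOOLS)
                },
                "tm_helices": tm,
                "er_motif": er,
                "gpi_anchor": gpi,
                "protein_length": length,
                "cys_count": min(cys, length),
            }
        )
    secretion = pd.DataFrame(rows)
    truth.ssp_ids = ssp_set
    truth.cysteine_rich_ids = cys_rich_set

    # CAZyme votes: planted genes then an equal number of single-call decoys
    vocab = ["GH5", "GH7", "GH17", "GT2", "GT4", "PL1", "CE4", "AA9", "CBM1", "CBM16"]
    pool = rng.choice(len(gene_ids), size=min(2 * cfg.n_cazyme, len(gene_ids)), replace=False)
    planted_genes = [gene_ids[i] for i in pool[: cfg.n_cazyme]]
    decoy_genes = [gene_ids[i] for i in pool[cfg.n_cazyme :]]
    cazy_rows = []
    for gid in planted_genes:
        n_fams = 1 + int(rng.integers(0, 2))
        fams = [vocab[i] for i in rng.choice(len(vocab), size=n_fams, replace=False)]
        calls: dict[str, list[str]] = {tool: [] for tool in CAZYME_TOOLS}
        for fam in fams:
            n_agree = 2 + int(rng.integers(0, 2))
            tools = rng.choice(len(CAZYME_TOOLS), size=n_agree, replace=False)
            for t in tools:
                calls[CAZYME_TOOLS[t]].append(fam)
        truth.cazyme_assignments[gid] = sorted(fams)
        cazy_rows.append({"gene_id": gid, **{t: ",".join(v) for t, v in calls.items()}})
    for gid in decoy_genes:
        tool = CAZYME_TOOLS[int(rng.integers(0, len(CAZYME_TOOLS)))]
        fam = vocab[int(rng.integers(0, len(vocab)))]
        row = {t: "" for t in CAZYME_TOOLS}
        row[tool] = fam
        cazy_rows.append({"gene_id": gid, **row})
    cazyme = pd.DataFrame(cazy_rows)
    return secretion, cazyme


@dataclass
class SimulationBundle:
    config: SimulationConfig
    genome: SimulatedGenome
    expression: pd.DataFrame
    families: list[tuple[RepeatFamilyAlignment, list[MutationCounts]]]
    secretion_votes: pd.DataFrame
    cazyme_votes: pd.DataFrame

    @property
    def truth(self) -> GroundTruth:
        return self.genome.truth


def simulate_all(config: SimulationConfig) -> SimulationBundle:
    genome = simulate_genome(config)
    expression = simulate_expression(genome.genes, genome.truth, config)
    families = simulate_families(config, genome.truth)
    secretion, cazyme = simulate_votes(genome.genes, genome.truth, config)
    return SimulationBundle(config, genome, expression, families, secretion, cazyme)


def write_bundle(bundle: SimulationBundle, out_dir: str | Path) -> None:
    """Write every simulated artifact in the formats the readers consume."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(bundle.genome.sequences, out / "genome.fa")
    write_gff3(bundle.genome.genes, out / "genes.gff3")
    write_repeats_bed(bundle.genome.repeats, out / "repeats.tsv")
    write_table(bundle.expression, out / "fpkm.tsv")
    votes_dir = out / "votes"
    votes_dir.mkdir(exist_ok=True)
    write_table(bundle.secretion_votes, votes_dir / "secretion.tsv")
    write_table(bundle.cazyme_votes, votes_dir / "cazyme.tsv")
    fam_dir = out / "families"
    fam_dir.mkdir(exist_ok=True)
    for aln, _ in bundle.families:
        records = [SequenceRecord(f"{aln.family_id}_model", aln.model)] + [
            SequenceRecord(cid, seq) for cid, seq in zip(aln.copy_ids, aln.copies)
        ]
        write_fasta(records, fam_dir / f"{aln.family_id}.aln.fa")
    bundle.truth.to_json(out / "truth.json")
    with open(out / "config.json", "w") as fh:
        json.dump(asdict(bundle.config), fh, indent=2, sort_keys=True)
        fh.write("\n")
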