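"""Synthetic fixture bundle with planted ground truth.

Generates everything the downstream stages consume — reference proteins,
a transcriptome with planted structural classes and splice variants,
orientation-aware alignment tables whose geometry reproduces the planted
classes under the annotation thresholds, and negative-binomial count
matrices with replicate block effects and condition-specific fold
changes — all driven by a single integer seed through deterministic
per-stage substreams.

Planted expression roles mirror the memory-type comparison framework:
``ltm_only`` genes respond only in long-term-memory conditioning,
``arm_only`` only in the anesthesia-resistant control, ``shared_same_direction``
in both with equal sign, ``opposing`` with opposite signs, and
``splice_specific`` genes express different splice variants in the two.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

from .annotate import AlignmentHit, ZONES
from .config import ConfigError, SimulationConfig, STRUCTURAL_CLASSES
from .de import DECall

_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]

# planted zone subsets for antisense-to-sense transcripts, weighted so
# that 3'UTR-touching alignments dominate as observed in wasp brains
_ZONE_CHOICES = [
    (frozenset({"three_prime_utr"}), 0.30),
    (frozenset({"cds", "three_prime_utr"}), 0.25),
    (frozenset({"five_prime_utr"}), 0.10),
    (frozenset({"five_prime_utr", "cds"}), 0.10),
    (frozenset({"cds"}), 0.10),
    (frozenset(ZONES), 0.15),
]


@dataclass
class PlantedTruth:
    """Ground truth of one simulated bundle.

    ``planted_class`` uses the five generator labels (sense,
    antisense_to_protein, antisense_to_sense, lncRNA, unknown);
    ``transcript_class`` the four annotation labels with antisense
    collapsed. ``true_log2fc`` holds only the planted nonzero entries;
    every other (transcript, contrast) pair is zero.
    """

    species: str
    gene_map: dict[str, str] = field(default_factory=dict)
    planted_class: dict[str, str] = field(default_factory=dict)
    transcript_class: dict[str, str] = field(default_factory=dict)
    antisense_to_protein: dict[str, bool] = field(default_factory=dict)
    antisense_to_sense: dict[str, bool] = field(default_factory=dict)
    sense_partner: dict[str, str] = field(default_factory=dict)
    a2s_interval: dict[str, tuple[int, int]] = field(default_factory=dict)
    zone_truth: dict[str, frozenset[str]] = field(default_factory=dict)
    cds_interval: dict[str, tuple[int, int]] = field(default_factory=dict)
    transcript_length: dict[str, int] = field(default_factory=dict)
    gene_role: dict[str, str] = field(default_factory=dict)
    true_log2fc: dict[str, dict[tuple[str, str], float]] = field(default_factory=dict)
    decoy_cov: dict[str, float] = field(default_factory=dict)
    zone_eligible_partners: set[str] = field(default_factory=set)

    @property
    def decoy_transcripts(self) -> set[str]:
        return set(self.decoy_cov)

    def transcripts(self) -> list[str]:
        return list(self.gene_map)

    def log2fc(self, transcript_id: str, contrast: tuple[str, str]) -> float:
        return self.true_log2fc.get(transcript_id, {}).get(contrast, 0.0)


def _streams(config: SimulationConfig) -> tuple[np.random.Generator, ...]:
    ss = np.random.SeedSequence(config.seed)
    return tuple(np.random.default_rng(s) for s in ss.spawn(3))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def generate_reference(
    config: SimulationConfig,
) -> tuple[dict[str, str], dict[str, str], dict[str, str], PlantedTruth]:
    """Build proteins, transcripts, the transcript->gene map and truth.

    Sense transcripts carry a planted CDS (0-based half-open, stop codon
    excluded) flanked by nonempty UTRs; splice variants share the CDS
    and differ in the 3' tail. Antisense-to-sense transcripts are the
    reverse complement of a partner window chosen to cover a planted
    zone subset. Identical (config, seed) gives byte-identical output.
    """
    config.validate()
    rng, _, _ = _streams(config)
    design = config.design
    truth = PlantedTruth(species=design.species)
    proteins: dict[str, str] = {}
    transcripts: dict[str, str] = {}

    classes = list(STRUCTURAL_CLASSES)
    probs = np.array([config.class_proportions.get(c, 0.0) for c in classes])
    gene_classes = [classes[i] for i in rng.choice(len(classes), size=config.n_genes, p=probs)]
    multi = rng.random(config.n_genes) < config.multi_transcript_fraction

    # role assignment over sense genes; splice-variant roles force two variants
    sense_gene_idx = [i for i, c in enumerate(gene_classes) if c == "sense"]
    perm = rng.permutation(len(sense_gene_idx))
    shuffled = [sense_gene_idx[i] for i in perm]
    role_of_gene_idx: dict[int, tuple[str, object]] = {}
    cursor = 0
    for eff in config.planted_effects:
        if cursor + eff.n_genes > len(shuffled):
            raise ConfigError(
                "not enough sense genes to host the planted effects; "
                "raise n_genes or the sense proportion"
            )
        for gi in shuffled[cursor : cursor + eff.n_genes]:
            role_of_gene_idx[gi] = (eff.role, eff)
            if eff.role == "splice_specific":
                multi[gi] = True
        cursor += eff.n_genes

    gene_ids = [f"g{i:05d}" for i in range(config.n_genes)]
    sense_transcripts: list[str] = []

    def add_transcript(tid, gid, seq, planted, collapsed):
        truth.gene_map[tid] = gid
        truth.planted_class[tid] = planted
        truth.transcript_class[tid] = collapsed
        truth.antisense_to_protein[tid] = planted == "antisense_to_protein"
        truth.antisense_to_sense[tid] = planted == "antisense_to_sense"
        truth.transcript_length[tid] = len(seq)
        transcripts[tid] = seq

    # pass 1: sense genes (antisense-to-sense partners must exist first)
    for i, gid in enumerate(gene_ids):
        if gene_classes[i] != "sense":
            continue
        utr5 = int(rng.integers(40, 150))
        n_aa = int(rng.integers(61, 301))
        utr3 = int(rng.integers(60, 300))
        cds = "ATG" + "".join(
            np.array(_NONSTOP_CODONS)[rng.integers(0, len(_NONSTOP_CODONS), n_aa - 1)]
        )
        seq = _random_seq(rng, utr5) + cds + "TAA" + _random_seq(rng, utr3)
        tid = f"{gid}_t1"
        add_transcript(tid, gid, seq, "sense", "sense")
        truth.cds_interval[tid] = (utr5, utr5 + 3 * n_aa)
        proteins[f"p_{gid}"] = str(Seq(cds).translate())
        sense_transcripts.append(tid)
        if multi[i]:
            tid2 = f"{gid}_t2"
            seq2 = seq[: utr5 + 3 * n_aa + 3] + _random_seq(rng, int(rng.integers(60, 300)))
            add_transcript(tid2, gid, seq2, "sense", "sense")
            truth.cds_interval[tid2] = (utr5, utr5 + 3 * n_aa)
            sense_transcripts.append(tid2)

    if not sense_transcripts and (
        config.class_proportions.get("antisense_to_sense", 0.0) > 0
        and any(c == "antisense_to_sense" for c in gene_classes)
    ):
        raise ConfigError("antisense_to_sense planted but no sense transcript exists")

    # a pool of reference proteins with no transcript in the assembly,
    # targeted by antisense-to-protein transcripts
    n_ext = max(8, sum(c == "antisense_to_protein" for c in gene_classes))
    for k in range(n_ext):
        n_aa = int(rng.integers(80, 250))
        proteins[f"p_ext{k:04d}"] = str(
            Seq(
                "ATG"
                + "".join(
                    np.array(_NONSTOP_CODONS)[
                        rng.integers(0, len(_NONSTOP_CODONS), n_aa - 1)
                    ]
                )
            ).translate()
        )

    zone_sets = [z for z, _ in _ZONE_CHOICES]
    zone_probs = np.array([w for _, w in _ZONE_CHOICES])
    margin = config.boundary_margin

    # pass 2: non-sense genes
    ext_counter = 0
    for i, gid in enumerate(gene_ids):
        cls = gene_classes[i]
        if cls == "sense":
            continue
        n_tx = 2 if multi[i] else 1
        for v in range(1, n_tx + 1):
            tid = f"{gid}_t{v}"
            if cls == "antisense_to_protein":
                seq = _random_seq(rng, int(rng.integers(300, 900)))
                add_transcript(tid, gid, seq, cls, "antisense")
            elif cls == "antisense_to_sense":
                partner = sense_transcripts[int(rng.integers(0, len(sense_transcripts)))]
                zones = zone_sets[int(rng.choice(len(zone_sets), p=zone_probs))]
                a, b = _interval_for_zones(
                    rng, zones, truth.cds_interval[partner], truth.transcript_length[partner]
                )
                qcov = float(rng.uniform(0.80 + 2 * margin, 0.98))
                tlen = max(int((b - a) / qcov), b - a)
                pseq = transcripts[partner]
                seq = _revcomp(pseq[a:b]) + _random_seq(rng, tlen - (b - a))
                add_transcript(tid, gid, seq, cls, "antisense")
                truth.sense_partner[tid] = partner
                truth.a2s_interval[tid] = (a, b)
                truth.zone_truth[tid] = zones
                truth.zone_eligible_partners.add(partner)
            elif cls == "lncRNA":
                add_transcript(tid, gid, _random_seq(rng, int(rng.integers(200, 1200))), cls, "lncRNA")
            else:
                add_transcript(tid, gid, _random_seq(rng, int(rng.integers(200, 1200))), cls, "unknown")
        ext_counter += 1

    # near-threshold decoys: unknown transcripts receiving one sense
    # protein hit whose coverage sits within half a margin of the sense
    # threshold; the strict rule decides their class, recorded in truth
    unknown_tids = [t for t, c in truth.planted_class.items() if c == "unknown"]
    sense_thr = 0.60
    for k, tid in enumerate(unknown_tids[: config.n_decoys]):
        kind = k % 3
        if kind == 0:
            cov = sense_thr
        elif kind == 1:
            cov = sense_thr + float(rng.uniform(margin / 4, margin / 2))
        else:
            cov = sense_thr - float(rng.uniform(margin / 4, margin / 2))
        truth.decoy_cov[tid] = cov
        if cov > sense_thr:
            truth.transcript_class[tid] = "sense"

    # planted fold changes; signs alternate within each effect so the
    # planted signal stays roughly mass-balanced per group (no external
    # normalization factors exist to absorb a net composition shift)
    for eff in config.planted_effects:
        genes = [gene_ids[gi] for gi, (r, e) in sorted(role_of_gene_idx.items()) if e is eff]
        for k, gid in enumerate(genes):
            truth.gene_role[gid] = eff.role
            sign = 1.0 if k % 2 == 0 else -1.0
            sign_arm = 1.0 if (k // 2) % 2 == 0 else -1.0
            tids = [t for t, g in truth.gene_map.items() if g == gid]
            arm = getattr(eff, "arm_type", "Glo-ARM")
            ltm_cts = [ct for ct in eff.conditioning_types if ct != arm]
            arm_cts = [ct for ct in eff.conditioning_types if ct == arm]

            def contrasts(cts):
                out = []
                for ct in cts:
                    tps = eff.time_points or design.time_points[ct]
                    out.extend((ct, tp) for tp in tps)
                return out

            def plant(tx_list, cts, value):
                for tx in tx_list:
                    d = truth.true_log2fc.setdefault(tx, {})
                    for contrast in contrasts(cts):
                        d[contrast] = value

            if eff.role == "ltm_only":
                plant(tids, ltm_cts or list(eff.conditioning_types), sign * eff.log2fc)
            elif eff.role == "arm_only":
                plant(tids, arm_cts or list(eff.conditioning_types), sign * eff.log2fc)
            elif eff.role == "shared_same_direction":
                plant(tids, ltm_cts, sign * eff.log2fc)
                plant(tids, arm_cts, sign * eff.log2fc)
            elif eff.role == "opposing":
                plant(tids, ltm_cts, sign * eff.log2fc)
                plant(tids, arm_cts, -sign * eff.log2fc)
            elif eff.role == "splice_specific":
                plant(tids[:1], ltm_cts, sign * eff.log2fc)
                plant(tids[1:2], arm_cts, sign_arm * eff.log2fc)
    return proteins, transcripts, dict(truth.gene_map), truth


def _interval_for_zones(
    rng: np.random.Generator,
    zones: frozenset[str],
    cds: tuple[int, int],
    length: int,
) -> tuple[int, int]:
    """Pick an interval on the sense transcript intersecting exactly the
    requested zone subset (coordinates 0-based half-open)."""
    c0, c1 = cds
    has5 = "five_prime_utr" in zones
    hascds = "cds" in zones
    has3 = "three_prime_utr" in zones
    if has5 and not hascds and not has3:
        a = int(rng.integers(0, max(1, c0 // 2)))
        b = int(rng.integers(a + 5, c0 + 1))
    elif has5 and hascds and not has3:
        a = int(rng.integers(0, c0 - 4))
        b = int(rng.integers(c0 + 5, c1 + 1))
    elif not has5 and hascds and not has3:
        a = int(rng.integers(c0, c1 - 30))
        b = int(rng.integers(a + 30, c1 + 1))
    elif not has5 and hascds and has3:
        a = int(rng.integers(c0, c1 - 4))
        b = int(rng.integers(c1 + 5, length + 1))
    elif not has5 and not hascds and has3:
        a = int(rng.integers(c1, length - 4))
        b = int(rng.integers(a + 5, length + 1))
    elif has5 and hascds and has3:
        a = int(rng.integers(0, c0 - 4))
        b = int(rng.integers(c1 + 5, length + 1))
    else:
        raise ConfigError(f"unsupported zone subset {set(zones)!r}")
    return a, b


def generate_alignment_table(
    truth: PlantedTruth, config: SimulationConfig
) -> list[AlignmentHit]:
    """Emit alignment hits whose geometry places every transcript on the
    correct side of every classification threshold by at least
    ``boundary_margin`` (decoy hits excepted, which sit within half a
    margin of the sense threshold)."""
    _, rng, _ = _streams(config)
    m = config.boundary_margin
    hits: list[AlignmentHit] = []
    ext_prots = [f"p_ext{k:04d}" for k in range(8)]

    for tid in truth.transcripts():
        cls = truth.planted_class[tid]
        gid = truth.gene_map[tid]
        length = truth.transcript_length[tid]
        if cls == "sense":
            c0, c1 = truth.cds_interval[tid]
            plen = (c1 - c0) // 3
            if tid in truth.zone_eligible_partners:
                cov = 1.0
                q0, q1 = c0, c1
            else:
                cov = float(rng.uniform(0.60 + m, 0.995))
                aa = max(1, int(round(cov * plen)))
                q0, q1 = c0, min(c1, c0 + 3 * aa)
            hits.append(
                AlignmentHit(
                    query_id=tid,
                    subject_id=f"p_{gid}",
                    subject_db="proteome",
                    orientation="sense",
                    identity=float(rng.uniform(0.7, 1.0)),
                    query_cov=(q1 - q0) / length,
                    subject_cov=cov,
                    q_start=q0,
                    q_end=q1,
                    s_start=0,
                    s_end=max(1, int(round(cov * plen))),
                )
            )
        elif cls == "antisense_to_protein":
            cov = float(rng.uniform(0.50 + m, 0.95))
            subj = ext_prots[int(rng.integers(0, len(ext_prots)))]
            span = max(30, int(0.5 * length))
            hits.append(
                AlignmentHit(
                    query_id=tid,
                    subject_id=subj,
                    subject_db="proteome" if rng.random() < 0.5 else "nr",
                    orientation="antisense",
                    identity=float(rng.uniform(0.6, 1.0)),
                    query_cov=span / length,
                    subject_cov=cov,
                    q_start=0,
                    q_end=span,
                    s_start=0,
                    s_end=max(1, span // 3),
                )
            )
        elif cls == "antisense_to_sense":
            partner = truth.sense_partner[tid]
            a, b = truth.a2s_interval[tid]
            hits.append(
                AlignmentHit(
                    query_id=tid,
                    subject_id=partner,
                    subject_db="self_transcriptome",
                    orientation="antisense",
                    identity=float(rng.uniform(0.95 + 2 * m, 1.0)),
                    query_cov=(b - a) / length,
                    subject_cov=(b - a) / truth.transcript_length[partner],
                    q_start=0,
                    q_end=b - a,
                    s_start=a,
                    s_end=b,
                )
            )
        elif cls == "lncRNA":
            db = "genome" if rng.random() < 0.8 else "nt"
            qcov = float(rng.uniform(0.80 + m, 1.0))
            span = max(1, int(qcov * length))
            hits.append(
                AlignmentHit(
                    query_id=tid,
                    subject_id=f"scaffold_{int(rng.integers(0, 50)):03d}",
                    subject_db=db,
                    orientation="sense" if rng.random() < 0.5 else "antisense",
                    identity=float(rng.uniform(0.95 + 2 * m, 1.0)),
                    query_cov=qcov,
                    subject_cov=0.01,
                    q_start=0,
                    q_end=span,
                    s_start=1000,
                    s_end=1000 + span,
                )
            )
        else:  # unknown: either silent or a clearly sub-threshold hit
            if rng.random() < 0.5 and tid not in truth.decoy_cov:
                cov = float(rng.uniform(0.2, 0.60 - 2 * m))
                span = max(30, int(0.3 * length))
                hits.append(
                    AlignmentHit(
                        query_id=tid,
                        subject_id=ext_prots[int(rng.integers(0, len(ext_prots)))],
                        subject_db="nr",
                        orientation="sense",
                        identity=float(rng.uniform(0.4, 0.9)),
                        query_cov=span / length,
                        subject_cov=cov,
                        q_start=0,
                        q_end=span,
                        s_start=0,
                        s_end=max(1, span // 3),
                    )
                )

    for tid, cov in truth.decoy_cov.items():
        length = truth.transcript_length[tid]
        span = max(30, int(0.5 * length))
        hits.append(
            AlignmentHit(
                query_id=tid,
                subject_id=ext_prots[0],
                subject_db="proteome",
                orientation="sense",
                identity=float(rng.uniform(0.6, 0.95)),
                query_cov=span / length,
                subject_cov=cov,
                q_start=0,
                q_end=span,
                s_start=0,
                s_end=max(1, span // 3),
            )
        )
    return hits


def nb_sample(
    rng: np.random.Generator, mu: np.ndarray, phi: np.ndarray
) -> np.ndarray:
    """Draw NB2 counts with mean ``mu`` and variance ``mu + phi mu^2``
    (elementwise); phi == 0 falls back to Poisson."""
    mu = np.asarray(mu, dtype=float)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), mu.shape)
    out = np.empty(mu.shape, dtype=np.int64)
    pois = phi <= 0
    if pois.any():
        out[pois] = rng.poisson(mu[pois])
    nb = ~pois
    if nb.any():
        r = 1.0 / phi[nb]
        p = r / (r + mu[nb])
        out[nb] = rng.negative_binomial(r, p)
    return out


def sample_table(config: SimulationConfig):
    """Sample metadata enumerating species x conditioning type x time
    point x replicate (plus unconditioned controls)."""
    import pandas as pd

    design = config.design
    rows = []
    for ct, tp in design.groups():
        for rep in range(1, design.n_replicates + 1):
            rows.append(
                {
                    "sample_id": f"{design.species}.{ct}.{tp}.r{rep}",
                    "species": design.species,
                    "conditioning_type": ct,
                    "time_point": tp,
                    "replicate": f"r{rep}",
                }
            )
    return pd.DataFrame(rows)


def generate_counts(truth: PlantedTruth, config: SimulationConfig):
    """NB count matrix + sample metadata under the planted design.

    count(t, s) ~ NB(mean = lib(s) * q(t) * exp(block(s)) * 2^lfc(t, group(s)),
    dispersion = phi0 + a / mean). Library sizes are drawn log-uniformly
    from ``library_size_range``; transcripts carrying planted effects are
    given moderate-to-high baseline abundance so the planted signal is
    identifiable, and a 5% low-abundance tail exercises the support
    filter.
    """
    import pandas as pd

    _, _, rng = _streams(config)
    design = config.design
    meta = sample_table(config)
    tids = truth.transcripts()
    n_tx = len(tids)
    n_s = len(meta)

    log_q = rng.normal(0.0, config.baseline_logmean_sd, size=n_tx)
    has_effect = np.array([tid in truth.true_log2fc for tid in tids])
    # effect carriers sit in the mid-abundance range: identifiable, yet
    # a small mass fraction of the bundle, as real DE transcripts are of
    # a full transcriptome (a net mass shift would otherwise leak into
    # the column-sum library sizes and bias every null fold change)
    log_q[has_effect] = np.clip(log_q[has_effect], -1.0, 0.0)
    low = (~has_effect) & (rng.random(n_tx) < 0.05)
    log_q[low] -= 8.0
    q = np.exp(log_q)
    q /= q.sum()

    lo, hi = config.library_size_range
    lib = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_s))
    blocks = {
        f"r{r}": rng.normal(0.0, config.block_effect_sd)
        for r in range(1, design.n_replicates + 1)
    }
    lfc = np.zeros((n_tx, n_s))
    for j, row in enumerate(meta.itertuples(index=False)):
        contrast = (row.conditioning_type, row.time_point)
        for i, tid in enumerate(tids):
            lfc[i, j] = truth.log2fc(tid, contrast)
    block_vec = np.array([blocks[r] for r in meta["replicate"]])
    mu = lib[None, :] * q[:, None] * np.exp(block_vec)[None, :] * 2.0**lfc
    mu = np.clip(mu, 1e-8, None)
    phi = config.dispersion_phi0 + config.dispersion_a / mu
    counts = nb_sample(rng, mu, phi)
    counts_df = pd.DataFrame(counts, index=tids, columns=list(meta["sample_id"]))
    counts_df.index.name = "transcript_id"
    return counts_df, meta


def truth_calls(truth: PlantedTruth, config: SimulationConfig) -> list[DECall]:
    """Noise-free DE calls read directly off the planted fold changes —
    the truth-bypassed input for comparison-stage recovery checks."""
    calls = []
    groups = [g for g in config.design.groups() if g[0] != config.design.unconditioned_label]
    for tid in truth.transcripts():
        for contrast in groups:
            lf = truth.log2fc(tid, contrast)
            if lf != 0.0:
                calls.append(
                    DECall(
                        transcript_id=tid,
                        conditioning_type=contrast[0],
                        time_point=contrast[1],
                        logfc=lf,
                        p_value=0.0,
                        direction="up" if lf > 0 else "down",
                        significant=True,
                    )
                )
    return calls


def expected_candidates(truth: PlantedTruth) -> dict[str, str | None]:
    """Expected comparison outcome per role gene: the retention rule, or
    None when the gene must be excluded/ignored by the LTM filter."""
    expected_rule = {
        "ltm_only": "absent_in_arm",
        "arm_only": None,
        "shared_same_direction": None,
        "opposing": "opposing",
        "splice_specific": "splice_variant",
    }
    return {g: expected_rule[r] for g, r in truth.gene_role.items()}


def make_ortholog_map(
    truth_a: PlantedTruth, truth_b: PlantedTruth, fraction: float = 0.78, seed: int = 7
) -> dict[str, str]:
    """Pair a fraction of the sense genes of two species into ortholog
    groups (both members map to the group id)."""
    rng = np.random.default_rng(seed)
    genes_a = sorted({g for t, g in truth_a.gene_map.items() if truth_a.planted_class[t] == "sense"})
    genes_b = sorted({g for t, g in truth_b.gene_map.items() if truth_b.planted_class[t] == "sense"})
    n = int(fraction * min(len(genes_a), len(genes_b)))
    pick_a = list(rng.permutation(genes_a))[:n]
    pick_b = list(rng.permutation(genes_b))[:n]
    out: dict[str, str] = {}
    for k, (ga, gb) in enumerate(zip(pick_a, pick_b)):
        og = f"OG{k:05d}"
        out[ga] = og
        out[gb] = og
    return out
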