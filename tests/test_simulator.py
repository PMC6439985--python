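"""Simulator: determinism, event semantics, ground-truth consistency."""

import numpy as np
import pytest

from splicealign.simulator import (
    PRESET_SCALES,
    evolve_branch,
    generate_dataset,
    generate_family,
    generate_root_gene,
    mean_pairwise_cds_identity,
)


def test_fixed_seed_reproduces_family_byte_identically(compact_config):
    a = generate_family("f", compact_config.scaled(0.15),
                        np.random.default_rng(5))
    b = generate_family("f", compact_config.scaled(0.15),
                        np.random.default_rng(5))
    assert [g.sequence for g in a.genes] == [g.sequence for g in b.genes]
    assert a.true_groups == b.true_groups
    assert {k: v.blocks for k, v in a.true_alignments.items()} == {
        k: v.blocks for k, v in b.true_alignments.items()
    }


def test_root_gene_respects_configured_bounds(compact_config):
    cfg = compact_config
    counts, lens = [], []
    for i in range(300):
        gene, _ = generate_root_gene(cfg, np.random.default_rng(i))
        counts.append(len(gene.exons))
        lens.extend(e.length_nt for e in gene.exons)
        assert len(gene.introns) == len(gene.exons) - 1
        assert all(s.startswith("GT") and s.endswith("AG") for s in gene.introns)
        assert gene.isoforms
    lo, hi = cfg.n_exons_range
    assert min(counts) >= lo and max(counts) <= hi
    assert min(lens) >= 3 * cfg.exon_codons_range[0]
    assert max(lens) <= 3 * cfg.exon_codons_range[1]


def test_zero_branch_length_is_identity(compact_config):
    gene, labeler = generate_root_gene(compact_config, np.random.default_rng(0))
    child = evolve_branch(gene, 0.0, compact_config,
                          np.random.default_rng(1), labeler)
    assert [e.codons for e in child.exons] == [e.codons for e in gene.exons]
    assert child.isoforms == gene.isoforms


def test_loss_only_config_shrinks_gene(compact_config):
    cfg = compact_config.scaled(1.0)
    import dataclasses

    cfg = dataclasses.replace(
        cfg,
        exon_duplication_rate=0.0, exon_gain_rate=0.0, exon_loss_rate=50.0,
        isoform_creation_rate=0.0, isoform_loss_rate=0.0,
        substitution_rate=0.0, indel_rate=0.0, intron_substitution_rate=0.0,
    )
    gene, labeler = generate_root_gene(cfg, np.random.default_rng(3))
    events = []
    child = evolve_branch(gene, 1.0, cfg, np.random.default_rng(4),
                          labeler, events)
    losses = [e for e in events if e["event"] == "exon_loss"]
    assert len(child.exons) == len(gene.exons) - len(losses)
    lost = {e["ancestry"] for e in losses}
    assert all(e.ancestry not in lost for e in child.exons)


def test_substitution_only_config_keeps_alignment_gapfree(compact_config):
    import dataclasses

    cfg = dataclasses.replace(
        compact_config.scaled(1.0),
        exon_duplication_rate=0.0, exon_gain_rate=0.0, exon_loss_rate=0.0,
        isoform_creation_rate=0.0, isoform_loss_rate=0.0,
        substitution_rate=0.3, indel_rate=0.0,
    )
    gene, labeler = generate_root_gene(cfg, np.random.default_rng(7))
    child = evolve_branch(gene, 1.0, cfg, np.random.default_rng(8), labeler)
    diffs = total = 0
    for pe, ce in zip(gene.exons, child.exons):
        assert pe.labels == ce.labels  # no indels: labels unchanged
        diffs += sum(1 for a, b in zip(pe.codons, ce.codons) if a != b)
        total += len(pe.codons)
    p = 1 - np.exp(-0.3)
    sd = np.sqrt(total * p * (1 - p))
    assert abs(diffs - total * p) < 5 * sd


def test_emitted_cds_lengths_divisible_by_three(compact_config):
    fam = generate_family("f", compact_config.scaled(0.15),
                          np.random.default_rng(23))
    for rec in fam.cds_records.values():
        assert len(rec.sequence) % 3 == 0


def test_truth_alignments_are_valid_and_self_exact(medium_divergence_family):
    fam = medium_divergence_family
    for (cid, gid), aln in fam.true_alignments.items():
        aln.validate()
        if fam.cds_records[cid].gene_id == gid:
            assert all(b.is_conserved for b in aln.blocks)
    # every CDS x gene ordered pair is present
    assert len(fam.true_alignments) == fam.n_cds * fam.n_genes


def test_exon_ancestry_traces_to_root_or_gain(medium_divergence_family):
    fam = medium_divergence_family
    for ancestries in fam.exon_ancestry.values():
        for anc in ancestries:
            base = anc.split(".")[0]
            assert base.startswith(("E", "G"))


def test_zero_event_family_orthology_is_one_group_per_root_isoform(
    compact_config,
):
    import dataclasses

    cfg = dataclasses.replace(
        compact_config.scaled(0.04),
        exon_duplication_rate=0.0, exon_gain_rate=0.0, exon_loss_rate=0.0,
        isoform_creation_rate=0.0, isoform_loss_rate=0.0, indel_rate=0.0,
    )
    fam = generate_family("z", cfg, np.random.default_rng(2))
    isoforms_per_gene = fam.n_cds // fam.n_genes
    assert fam.n_cds == isoforms_per_gene * fam.n_genes
    # every group holds the same isoform replicated across all genes
    for group in fam.true_groups:
        assert len(group) == fam.n_genes
        suffixes = {cid.split(".", 1)[1] for cid in group}
        assert len(suffixes) == 1


def test_gain_breaks_orthology_between_carriers_and_non_carriers(
    compact_config,
):
    """A CDS carrying a gained exon can never be a true ortholog of a CDS
    lacking it: the ancestry bijection fails."""
    fam = None
    for seed in range(40):
        cand = generate_family("g", compact_config.scaled(0.3),
                               np.random.default_rng(seed))
        gains = {
            anc
            for ancs in fam_anc(cand).values()
            for anc in ancs
            if anc.startswith("G")
        }
        if gains:
            fam = cand
            break
    assert fam is not None, "no family with an exon gain in 40 seeds"
    carriers = {
        cid for cid, ancs in fam.cds_ancestry.items()
        if any(a.startswith("G") for a in ancs)
    }
    assert carriers
    for group in fam.true_groups:
        # a group never mixes carriers of a gained exon with non-carriers
        assert not (group & carriers) or group <= carriers


def fam_anc(fam):
    return fam.cds_ancestry


def test_dataset_shape_and_determinism(compact_config):
    ds1 = generate_dataset("small", 4, seed=9, config=compact_config)
    ds2 = generate_dataset("small", 4, seed=9, config=compact_config)
    assert len(ds1) == 4
    for f1, f2 in zip(ds1, ds2):
        assert f1.n_genes == 5
        lo, hi = compact_config.cds_total_range
        assert lo <= f1.n_cds <= hi
        assert [g.sequence for g in f1.genes] == [g.sequence for g in f2.genes]


def test_preset_identity_ordering(compact_config):
    means = {}
    for preset in PRESET_SCALES:
        fams = generate_dataset(preset, 10, seed=3, config=compact_config)
        means[preset] = float(
            np.mean([mean_pairwise_cds_identity(f) for f in fams])
        )
    assert means["small"] > means["medium"] > means["large"]


def test_unknown_preset_rejected():
    with pytest.raises(ValueError):
        generate_dataset("huge", 1, 0)
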