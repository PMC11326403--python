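"""PAS calling: tag extraction, clustering, filtering, annotation,
normalization."""

import numpy as np
import pandas as pd
import pytest

from apaclock import pas, sim


def tags_frame(rows):
    """rows of (chrom, strand, end3, sample_id)"""
    return pd.DataFrame(rows, columns=pas.TAG_COLUMNS)


# ---------------------------------------------------------------------------
# extraction


SAM_TEXT = """\
@HD\tVN:1.6\tSO:coordinate
@SQ\tSN:chr1\tLN:100000
fwd\t0\tchr1\t100\t60\t51M\t*\t0\t0\t{seq}\t*
rev\t16\tchr1\t100\t60\t51M\t*\t0\t0\t{seq}\t*
multi\t0\tchr1\t500\t0\t51M\t*\t0\t0\t{seq}\t*\tNH:i:4
sec\t256\tchr1\t700\t60\t51M\t*\t0\t0\t{seq}\t*
unmap\t4\t*\t0\t0\t*\t*\t0\t0\t{seq}\t*
""".format(seq="A" * 51)


def test_extract_tags_sam_conventions(tmp_path):
    p = tmp_path / "a.sam"
    p.write_text(SAM_TEXT)
    tags = pas.extract_tags_sam(p, sample_id="s1")
    # span 100..150 (51M from 1-based 100): + -> 150, - -> 100
    by = tags.set_index(tags.index)
    assert len(tags) == 2
    fwd = tags[tags["strand"] == "+"].iloc[0]
    rev = tags[tags["strand"] == "-"].iloc[0]
    assert fwd["end3"] == 150
    assert rev["end3"] == 100
    assert tags.attrs["skipped"] == {
        "unmapped": 1, "secondary": 1, "supplementary": 0, "multi": 1
    }


def test_extract_tags_bed_conventions(tmp_path):
    p = tmp_path / "a.bed"
    p.write_text(
        "chr1\t99\t150\ts1:r1\t0\t+\n"
        "chr1\t99\t150\ts1:r2\t0\t-\n"
    )
    tags = pas.extract_tags_bed(p)
    assert list(tags["end3"]) == [150, 100]
    assert list(tags["sample_id"]) == ["s1", "s1"]


def test_extract_tags_multiplicity_preserved(tmp_path):
    p = tmp_path / "a.bed"
    p.write_text("chr1\t99\t100\ts:1\t0\t+\n" * 3)
    assert len(pas.extract_tags_bed(p)) == 3


# ---------------------------------------------------------------------------
# clustering


def test_cluster_spec_examples():
    rows = (
        [("chr1", "+", 100, "s") for _ in range(5)]
        + [("chr1", "+", 110, "s") for _ in range(2)]
        + [("chr1", "+", 140, "s")]
    )
    pacs = pas.cluster_pas(tags_frame(rows))
    assert len(pacs) == 2
    first, second = pacs.meta.iloc[0], pacs.meta.iloc[1]
    assert (first["start"], first["end"], first["peak"]) == (100, 110, 100)
    assert (second["start"], second["end"], second["peak"]) == (140, 140, 140)

    chained = pas.cluster_pas(
        tags_frame([("chr1", "+", p, "s") for p in (100, 125, 150)])
    )
    assert len(chained) == 1
    assert (chained.meta.iloc[0]["start"], chained.meta.iloc[0]["end"]) == (100, 150)


def test_cluster_order_invariance():
    rng = np.random.default_rng(4)
    ends = rng.integers(1, 2000, size=120)
    rows = [("chr1", "+", int(e), f"s{e % 3}") for e in ends]
    a = pas.cluster_pas(tags_frame(rows))
    rng.shuffle(rows)
    b = pas.cluster_pas(tags_frame(rows))
    pd.testing.assert_frame_equal(a.meta, b.meta)
    pd.testing.assert_frame_equal(a.counts_raw, b.counts_raw)


def brute_force_clusters(endpoints, window=25):
    """O(n^2) single-linkage oracle: repeatedly merge any two groups
    containing endpoints <= window apart."""
    groups = [{e} for e in set(endpoints)]
    merged = True
    while merged:
        merged = False
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                if any(abs(a - b) <= window for a in groups[i] for b in groups[j]):
                    groups[i] |= groups.pop(j)
                    merged = True
                    break
            if merged:
                break
    return sorted(tuple(sorted(g)) for g in groups)


def test_cluster_matches_bruteforce_oracle():
    rng = np.random.default_rng(7)
    for _ in range(150):
        n = int(rng.integers(1, 200))
        ends = rng.integers(1, 3000, size=n)
        got = pas.cluster_pas(
            tags_frame([("chr1", "+", int(e), "s") for e in ends])
        )
        want = brute_force_clusters(ends)
        have = [
            (int(r["start"]), int(r["end"]))
            for _, r in got.meta.iterrows()
        ]
        assert [(g[0], g[-1]) for g in want] == sorted(have)


def test_cluster_tag_conservation():
    rng = np.random.default_rng(9)
    rows = [
        ("chr1", "+", int(rng.integers(1, 500)), f"s{int(rng.integers(3))}")
        for _ in range(300)
    ]
    df = tags_frame(rows)
    pacs = pas.cluster_pas(df)
    per_sample_in = df.groupby("sample_id").size()
    per_sample_out = pacs.counts_raw.sum(axis=0)
    assert (per_sample_in == per_sample_out).all()


def test_cluster_peak_tiebreak_3prime_most():
    # 100 and 110 both have 2 reads: + strand picks 110, - picks 100
    rows = [("chr1", "+", p, "s") for p in (100, 100, 110, 110)]
    assert pas.cluster_pas(tags_frame(rows)).meta.iloc[0]["peak"] == 110
    rows = [("chr1", "-", p, "s") for p in (100, 100, 110, 110)]
    assert pas.cluster_pas(tags_frame(rows)).meta.iloc[0]["peak"] == 100


# ---------------------------------------------------------------------------
# filtering


def make_pacs(counts, samples):
    n = len(counts)
    meta = pd.DataFrame(
        {"chrom": ["chr1"] * n, "strand": ["+"] * n,
         "start": range(100, 100 + n), "end": range(100, 100 + n),
         "peak": range(100, 100 + n)}
    )
    meta.index.name = "pas_id"
    raw = pd.DataFrame(counts, columns=samples)
    raw.index.name = "pas_id"
    return pas.PacSet(meta, raw)


@pytest.mark.parametrize(
    "libsize, counts, kept",
    [
        (1_600_000, (3, 3, 3, 0, 0), True),    # small-library branch, >=3 of 3
        (2_000_000, (3, 3, 3, 0, 0), False),   # large libraries need >= 4
        (1_600_000, (4, 4, 0, 0, 0), False),   # only 2 qualifying samples
        (1_700_000, (3, 3, 3, 0, 0), False),   # exactly 1.7M counts as large
    ],
)
def test_filter_pacs_library_size_rule(libsize, counts, kept):
    samples = [f"s{i}" for i in range(5)]
    pacs = make_pacs([counts], samples)
    out = pas.filter_pacs(
        pacs,
        {s: libsize for s in samples},
        {s: "g1" for s in samples},
    )
    assert (len(out) == 1) is kept


def test_filter_pacs_any_group_qualifies():
    samples = [f"a{i}" for i in range(5)] + [f"b{i}" for i in range(5)]
    groups = {s: s[0] for s in samples}
    sizes = {s: 1_000_000 for s in samples}
    pacs = make_pacs([(0,) * 5 + (3, 3, 3, 0, 0)], samples)
    assert len(pas.filter_pacs(pacs, sizes, groups)) == 1


def test_filter_pacs_missing_group_errors():
    samples = ["s0", "s1", "s2", "s3", "s4"]
    pacs = make_pacs([(1,) * 5], samples)
    with pytest.raises(ValueError, match="group"):
        pas.filter_pacs(pacs, {s: 1 for s in samples}, {"s0": "g"})


# ---------------------------------------------------------------------------
# annotation


@pytest.fixture(scope="module")
def annotated_world():
    fasta, gtf, models = sim.simulate_genome(10, seed=21)
    return models, sim.models_to_gene_annots(models)


def test_annotate_planted_sites_roundtrip(annotated_world):
    """Every planted PAS, turned into a 1-read cluster at its coordinate,
    gets back its own gene and region class."""
    models, annots = annotated_world
    rows, want = [], []
    for m in models:
        for coord, cls, _ in m.pas_sites:
            rows.append((m.chrom, m.strand, coord, "s"))
            want.append((m.gene_id, cls))
    pacs = pas.cluster_pas(tags_frame(rows), window=0)
    ann = pas.annotate_pacs(pacs, annots)
    got = list(zip(ann.meta["gene_symbol"], ann.meta["region_class"]))
    # clusters are sorted by position; rebuild wanted in the same order
    order = ann.meta[["chrom", "strand", "peak"]].itertuples(index=False)
    by_pos = {
        (m.chrom, m.strand, coord): (m.gene_id, cls)
        for m in models
        for coord, cls, _ in m.pas_sites
    }
    want_sorted = [by_pos[(c, s, p)] for c, s, p in order]
    assert got == want_sorted


def test_annotate_distal_and_intergenic(annotated_world):
    models, annots = annotated_world
    m = next(x for x in models if x.strand == "+")
    sign = 1
    distal_peak = m.tx_end3 + 30
    far_peak = m.tx_end3 + 50_000_000
    pacs = pas.cluster_pas(
        tags_frame([(m.chrom, m.strand, distal_peak, "s"),
                    (m.chrom, m.strand, far_peak, "s")]),
        window=0,
    )
    ann = pas.annotate_pacs(pacs, annots)
    classes = dict(zip(ann.meta["peak"], ann.meta["region_class"]))
    assert classes[distal_peak] == pas.REGION_UTR3_DISTAL
    assert classes[far_peak] == pas.REGION_INTERGENIC


def test_apas_per_gene_consistency(annotated_world):
    models, annots = annotated_world
    m = max(models, key=lambda x: x.apa_count)
    rows = [(m.chrom, m.strand, c, "s") for c, _, _ in m.pas_sites]
    ann = pas.annotate_pacs(pas.cluster_pas(tags_frame(rows), window=0), annots)
    mine = ann.meta[ann.meta["gene_symbol"] == m.gene_id]
    assert (mine["apas_per_gene"] == len(mine)).all()


def test_apa_spectrum_hand_count():
    samples = ["s"]
    meta = pd.DataFrame(
        {"chrom": ["chr1"] * 3, "strand": ["+"] * 3,
         "start": [1, 2, 3], "end": [1, 2, 3], "peak": [1, 2, 3],
         "gene_symbol": ["A", "B", "B"],
         "region_class": [pas.REGION_UTR3_TERMINAL] * 3,
         "apas_per_gene": [1, 2, 2]}
    )
    raw = pd.DataFrame({"s": [1, 1, 1]})
    hist, frac2, frac3 = pas.apa_spectrum(pas.PacSet(meta, raw))
    assert frac2 == pytest.approx(2 / 3)
    assert frac3 == 0.0
    assert hist.to_dict() == {1: 1, 2: 2}


# ---------------------------------------------------------------------------
# normalization


def test_normalize_arithmetic_and_scale_invariance():
    samples = ["s1"]
    pacs = make_pacs([(200,), (1_999_800,)], samples)
    out = pas.normalize(pacs, drop_mito=False)
    assert out.counts_norm.iloc[0, 0] == pytest.approx(1000.0)
    doubled = make_pacs([(400,), (3_999_600,)], samples)
    out2 = pas.normalize(doubled, drop_mito=False)
    pd.testing.assert_frame_equal(out.counts_norm, out2.counts_norm)


def test_normalize_drops_mito_and_rescales():
    meta = pd.DataFrame(
        {"chrom": ["chr1", "chrM"], "strand": ["+", "+"],
         "start": [1, 2], "end": [1, 2], "peak": [1, 2]}
    )
    raw = pd.DataFrame({"s": [100, 900]})
    out = pas.normalize(pas.PacSet(meta, raw))
    assert len(out) == 1
    assert out.counts_norm["s"].sum() == pytest.approx(1e7)


def test_normalize_zero_library_errors():
    pacs = make_pacs([(0,)], ["empty"])
    with pytest.raises(ValueError, match="empty"):
        pas.normalize(pacs, drop_mito=False)


def test_filter_normalize_permutation_equivariance():
    rng = np.random.default_rng(13)
    samples = [f"s{i}" for i in range(5)]
    counts = rng.integers(0, 30, size=(20, 5))
    pacs = make_pacs(counts, samples)
    sizes = {s: 1_000_000 for s in samples}
    groups = {s: "g" for s in samples}
    base = pas.normalize(
        pas.filter_pacs(pacs, sizes, groups), drop_mito=False
    )
    perm = ["s3", "s0", "s4", "s1", "s2"]
    pacs_p = pas.PacSet(pacs.meta.copy(), pacs.counts_raw[perm].copy())
    out_p = pas.normalize(
        pas.filter_pacs(pacs_p, sizes, groups), drop_mito=False
    )
    pd.testing.assert_frame_equal(base.counts_norm[perm], out_p.counts_norm)
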