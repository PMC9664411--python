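"""Locus model: guide localization, product prediction, feature derivation."""

import re

import numpy as np
import pytest

from exciseq.dna import revcomp
from exciseq.locus import (
    AmbiguousGuideError,
    FeatureSet,
    GuideNotFoundError,
    InvalidPamError,
    build_locus,
    derive_features,
    expected_products,
    find_guide_site,
)

from conftest import BASES, make_random_locus

PAM_RE = re.compile(r"[ACGT]{2}G[AG][AG]T")


def _oracle_scan(reference: str, protospacer: str):
    """Brute-force regex scan for protospacer+PAM sites on both strands."""
    L = len(protospacer)
    raw, valid = [], []
    for m in re.finditer(f"(?={re.escape(protospacer)})", reference):
        s = m.start()
        pam = reference[s + L : s + L + 6]
        raw.append(("+", s, pam))
        if len(pam) == 6 and PAM_RE.fullmatch(pam):
            valid.append(("+", s, s + L - 3))
    rc = revcomp(protospacer)
    for m in re.finditer(f"(?={re.escape(rc)})", reference):
        s = m.start()
        pam = revcomp(reference[s - 6 : s]) if s >= 6 else ""
        raw.append(("-", s, pam))
        if len(pam) == 6 and PAM_RE.fullmatch(pam):
            valid.append(("-", s, s + 3))
    return raw, valid


class TestFindGuideSite:
    def test_plus_strand_cut_is_three_nt_from_pam(self):
        """Protospacer ending at offset 100 with PAM at 100..106 cuts at 97."""
        rng = np.random.default_rng(1)
        seq = list(BASES[rng.integers(0, 4, size=200)])
        proto = "".join(BASES[rng.integers(0, 4, size=21)])
        seq[79:100] = list(proto)
        seq[100:106] = list("TTGAAT")
        ref = "".join(seq)
        site = find_guide_site(ref, proto)
        assert (site.strand, site.match_start, site.cut_pos) == ("+", 79, 97)
        assert site.pam == "TTGAAT"

    def test_minus_strand_symmetry(self):
        """The same guide found on the - strand yields the mirrored coordinate."""
        rng = np.random.default_rng(2)
        seq = list(BASES[rng.integers(0, 4, size=200)])
        proto = "".join(BASES[rng.integers(0, 4, size=21)])
        seq[79:100] = list(proto)
        seq[100:106] = list("TTGAAT")
        ref = "".join(seq)
        site_fwd = find_guide_site(ref, proto)
        site_rev = find_guide_site(revcomp(ref), proto)
        assert site_rev.strand == "-"
        assert site_rev.cut_pos == len(ref) - site_fwd.cut_pos

    def test_agrees_with_exhaustive_scan_oracle(self):
        """Guide search matches a regex-based scan on 1,000 random references."""
        rng = np.random.default_rng(3)
        n_found = 0
        for _ in range(1000):
            seq = list(BASES[rng.integers(0, 4, size=80)])
            proto = "".join(BASES[rng.integers(0, 4, size=21)])
            pos = int(rng.integers(0, 80 - 27))
            seq[pos : pos + 21] = list(proto)
            if rng.random() < 0.8:  # sometimes leave the PAM random
                pam = "".join(
                    [BASES[rng.integers(0, 4)], BASES[rng.integers(0, 4)], "G",
                     "AG"[rng.integers(0, 2)], "AG"[rng.integers(0, 2)], "T"]
                )
                seq[pos + 21 : pos + 27] = list(pam)
            ref = "".join(seq)
            _, valid = _oracle_scan(ref, proto)
            if len(valid) == 1:
                site = find_guide_site(ref, proto)
                assert site.cut_pos == valid[0][2]
                assert site.strand == valid[0][0]
                n_found += 1
            elif len(valid) > 1:
                with pytest.raises(AmbiguousGuideError):
                    find_guide_site(ref, proto)
            else:
                with pytest.raises((GuideNotFoundError, InvalidPamError)):
                    find_guide_site(ref, proto)
        assert n_found > 500  # the oracle actually exercised the happy path

    def test_error_classes(self):
        ref = "ACGT" * 30
        with pytest.raises(GuideNotFoundError):
            find_guide_site(ref, "TTTTTTTTTTTTTTTTTTTTT")
        rng = np.random.default_rng(4)
        seq = list(BASES[rng.integers(0, 4, size=120)])
        proto = "".join(BASES[rng.integers(0, 4, size=21)])
        seq[10:31] = list(proto)
        seq[31:37] = list("AACCTT")  # fails NNGRRT
        with pytest.raises(InvalidPamError):
            find_guide_site("".join(seq), proto)


class TestExpectedProducts:
    def test_assay_scale_deletion_product(self, locus):
        """An 833 bp amplicon with cuts 387 bp apart yields a 446 bp product."""
        assert len(locus.reference) == 833
        assert locus.intercut_distance == 387
        products = expected_products(locus)
        assert len(products["deletion"]) == 446
        assert len(products["inversion"]) == 833

    def test_inversion_is_in_place_revcomp(self, locus):
        products = expected_products(locus)
        c5, c3 = locus.cut5, locus.cut3
        inv = products["inversion"]
        assert inv[c5:c3] == revcomp(locus.reference[c5:c3])
        assert inv[:c5] == locus.reference[:c5]
        assert inv[c3:] == locus.reference[c3:]

    def test_length_conservation_on_random_loci(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            loc = make_random_locus(rng)
            products = expected_products(loc)
            assert len(products["deletion"]) + loc.intercut_distance == len(loc.reference)
            assert len(products["inversion"]) == len(loc.reference)

    def test_minimal_intercut_distance(self):
        """With cuts one base apart the deletion product loses exactly 1 nt."""
        rng = np.random.default_rng(6)
        loc = make_random_locus(rng)
        # rebuild with synthetic cut coordinates via direct product arithmetic
        ref = loc.reference
        c5 = 300
        deletion = ref[:c5] + ref[c5 + 1 :]
        assert len(deletion) == len(ref) - 1

    def test_guide_order_violation(self):
        from exciseq.locus import LocusModel

        rng = np.random.default_rng(7)
        loc = make_random_locus(rng)
        with pytest.raises(ValueError, match="guide order"):
            LocusModel(
                reference=loc.reference,
                exon_interval=loc.exon_interval,
                guide5=loc.guide3,  # swapped on purpose
                guide3=loc.guide5,
            )


class TestDeriveFeatures:
    def test_intact5_centering_convention(self, locus):
        fs = derive_features(locus, k=25, n_per_junction=1)
        c5 = locus.cut5
        assert fs.features["intact5"] == [locus.reference[c5 - 12 : c5 + 13]]

    def test_fusion_kmer_straddles_deletion_seam(self, locus):
        """The fusion k-mer equals the seam-centered slice of the deletion."""
        fs = derive_features(locus, k=25, n_per_junction=1)
        deletion = expected_products(locus)["deletion"]
        c5 = locus.cut5
        assert fs.features["fusion"] == [deletion[c5 - 12 : c5 + 13]]

    def test_junction_kmers_absent_from_reference(self, features, locus):
        """Edit-diagnostic k-mers never occur in the unedited amplicon."""
        import edlib

        for name in ("fusion", "inversion_left", "inversion_right"):
            for kmer in features.features[name]:
                for target in (locus.reference, revcomp(locus.reference)):
                    res = edlib.align(kmer, target, mode="HW", task="distance",
                                      k=features.max_dist)
                    assert res["editDistance"] == -1

    def test_junction_kmers_present_in_own_product(self, features, locus):
        products = expected_products(locus)
        assert all(k in locus.reference for k in features.features["intact5"])
        assert all(k in locus.reference for k in features.features["intact3"])
        assert all(k in products["deletion"] for k in features.features["fusion"])
        assert all(k in products["inversion"] for k in features.features["inversion_left"])
        assert all(k in products["inversion"] for k in features.features["inversion_right"])

    def test_aav_backbone_matching_reference_rejected(self):
        rng = np.random.default_rng(8)
        loc = make_random_locus(rng)
        clash = loc.reference[50 : 50 + 200]  # a backbone sharing amplicon sequence
        bad = build_locus(
            loc.reference,
            loc.guide5.protospacer,
            loc.guide3.protospacer,
            exon_interval=loc.exon_interval,
            aav_backbones=[("clash", clash)],
        )
        with pytest.raises(ValueError, match="non-diagnostic"):
            derive_features(bad)

    def test_aav_features_enumerate_both_orientations(self, features, locus):
        for vname, seq in locus.aav_backbones:
            fwd = features.features[f"aav:{vname}:fwd"]
            rev = features.features[f"aav:{vname}:rev"]
            assert len(fwd) == len(seq) - features.k + 1
            assert set(rev) == {revcomp(km) for km in fwd}

    def test_kmer_collision_across_features_rejected(self):
        fs = FeatureSet(k=4, max_dist=0,
                        features={"a": ["ACGT"], "b": ["ACGT"]})
        with pytest.raises(ValueError, match="collision"):
            fs.validate()

    def test_stagger_too_wide_rejected(self, locus):
        with pytest.raises(ValueError, match="stagger"):
            derive_features(locus, k=25, n_per_junction=3, stagger=10)

    def test_tsv_round_trip(self, features, tmp_path):
        path = tmp_path / "features.tsv"
        features.to_tsv(path)
        loaded = FeatureSet.from_tsv(path)
        assert loaded.k == features.k
        assert loaded.max_dist == features.max_dist
        assert loaded.features == features.features


def test_load_locus_from_yaml_config(tmp_path, locus):
    """YAML config with a backbone FASTA reproduces the in-memory model."""
    import yaml

    fasta = tmp_path / "aav.fasta"
    with open(fasta, "w") as fh:
        for name, seq in locus.aav_backbones:
            fh.write(f">{name}\n{seq}\n")
    cfg = {
        "reference": locus.reference,
        "exon": list(locus.exon_interval),
        "guides": {
            "five_prime": locus.guide5.protospacer,
            "three_prime": locus.guide3.protospacer,
        },
        "aav_backbones": "aav.fasta",
        "primers": list(locus.primers),
    }
    path = tmp_path / "locus.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh)

    from exciseq.locus import load_locus

    loaded = load_locus(path)
    assert loaded.reference == locus.reference
    assert (loaded.cut5, loaded.cut3) == (locus.cut5, locus.cut3)
    assert loaded.exon_interval == locus.exon_interval
    assert loaded.aav_backbones == locus.aav_backbones


def test_revcomp_involution():
    rng = np.random.default_rng(9)
    for _ in range(50):
        s = "".join(BASES[rng.integers(0, 4, size=rng.integers(1, 80))])
        assert revcomp(revcomp(s)) == s
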