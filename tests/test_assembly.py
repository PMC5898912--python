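"""Type IIS digestion geometry, Golden Gate ligation graph, donor assembly,
and GenBank round trips."""

import numpy as np
import pytest

import introntrap as it
from introntrap.construct_assembly import (CASSETTE_TOPOLOGIES, carrier_for,
                                           validate_cassette)
from introntrap.enzymes import get_enzyme
from introntrap.seqtools import circular_equal, revcomp


class TestDigest:
    def test_hand_computed_bsai_cut(self):
        # GGTCTC(1/5): top cut 1 nt after the site, bottom 5 nt after
        enz = get_enzyme("BsaI")
        seq = "AAAAAAAAAA" + "GGTCTC" + "TACGTCCC" + "TTTTTTTTTT"
        frags = it.typeIIS_digest(seq, "linear", enz)
        assert len(frags) == 2
        left, right = frags
        # 4-nt 5' overhang = bases at offsets +1..+5 downstream of the site
        assert right.left_overhang == ("ACGT", "5'")
        assert left.right_overhang == ("ACGT", "5'")
        assert left.body == "AAAAAAAAAA" + "GGTCTC" + "T"
        assert left.left_overhang == ("", "blunt")

    def test_no_sites_single_blunt_fragment(self):
        enz = get_enzyme("BsaI")
        (frag,) = it.typeIIS_digest("ACGT" * 30, "linear", enz)
        assert frag.body == "ACGT" * 30
        assert frag.left_overhang == ("", "blunt")
        assert frag.right_overhang == ("", "blunt")

    def test_reverse_strand_site_mirrors_forward(self):
        enz = get_enzyme("BsaI")
        fwd = "A" * 20 + "GGTCTC" + "CATCGTAG" + "T" * 20
        rev = revcomp(fwd)
        f1 = it.typeIIS_digest(fwd, "linear", enz)
        f2 = it.typeIIS_digest(rev, "linear", enz)
        assert [f.body for f in f2] == [revcomp(f.body) for f in reversed(f1)]
        assert f2[1].left_overhang[0] == revcomp(f1[1].left_overhang[0])

    def test_cut_outside_linear_molecule_skipped(self):
        enz = get_enzyme("BsaI")
        seq = "A" * 10 + "GGTCTC" + "AB"[0]  # cut would fall past the end
        (frag,) = it.typeIIS_digest(seq, "linear", enz)
        assert frag.body == seq

    def test_conservation_of_bases(self):
        enz = get_enzyme("BbsI")
        rng = np.random.default_rng(5)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 3000))
        frags = it.typeIIS_digest(seq, "linear", enz)
        assert "".join(f.left_overhang[0] + f.body for f in frags) == seq

    def test_circular_digest_covers_molecule(self):
        enz = get_enzyme("BsaI")
        seq = ("TTTT" + "C" * 50 + "GGTCTC" + "A" + "GGAG"
               + "C" * 60 + "GGTCTC" + "A" + "TACT" + "C" * 30)
        frags = it.typeIIS_digest(seq, "circular", enz)
        assert len(frags) == 2
        assert sum(len(f.left_overhang[0]) + len(f.body) for f in frags) == len(seq)
        assert {f.left_overhang[0] for f in frags} == {"GGAG", "TACT"}

    def test_agrees_with_independent_restriction_catalogue(self):
        """Cross-check cut coordinates against Bio.Restriction."""
        from Bio.Restriction import BsaI
        from Bio.Seq import Seq
        rng = np.random.default_rng(11)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 5000))
        ours = sorted(ct for ct, _ in
                      it.construct_assembly._cut_events(seq, "linear",
                                                        get_enzyme("BsaI")))
        theirs = sorted(p - 1 for p in BsaI.search(Seq(seq)))   # 1-based
        assert ours == theirs


def random_circle_with_distinct_overhangs(rng, n_frags):
    """Random circular molecule containing n BsaI cassettes with pairwise
    distinct, non-complementary overhangs."""
    enz = get_enzyme("BsaI")
    overhangs = []
    while len(overhangs) < n_frags:
        o = "".join("ACGT"[i] for i in rng.integers(0, 4, 4))
        if o not in overhangs and revcomp(o) not in overhangs and o != revcomp(o):
            overhangs.append(o)
    parts = []
    for k in range(n_frags):
        body = "".join("ACGT"[i] for i in rng.integers(0, 4, rng.integers(40, 120)))
        body = body.replace("GGTCTC", "GGACTC").replace("GAGACC", "GAGTCC")
        parts.append(overhangs[k] + body)
    return "".join(parts), overhangs


class TestAssemble:
    def test_digest_then_assemble_reproduces_random_circles(self):
        """assemble(digest(X)) == X (up to rotation/strand) for random
        circular molecules whose cut overhangs are all distinct."""
        rng = np.random.default_rng(7)
        enz = get_enzyme("BsaI")
        done = 0
        while done < 100:
            n = int(rng.integers(2, 6))
            X = ""
            for _k in range(n):
                b = "".join("ACGT"[i]
                            for i in rng.integers(0, 4, rng.integers(60, 200)))
                b = b.replace("GGTCTC", "GGACTC").replace("GAGACC", "GAGTCC")
                X += b + enz.recognition
            frags = it.typeIIS_digest(X, "circular", enz)
            if len(frags) != n:
                continue
            ovs = [f.left_overhang[0] for f in frags]
            spelled = ovs + [revcomp(o) for o in ovs]
            if len(set(spelled)) != 2 * n:     # collision or palindrome: skip
                continue
            order = rng.permutation(n)
            product = it.gga_assemble([frags[i] for i in order])
            assert circular_equal(product.sequence, X)
            assert len(product.sequence) == len(X)
            done += 1

    def test_incompatible_overhangs_error(self):
        a = it.DigestFragment(body="AAAA", left_overhang=("GGAG", "5'"),
                              right_overhang=("TACT", "5'"))
        b = it.DigestFragment(body="CCCC", left_overhang=("AATG", "5'"),
                              right_overhang=("GCTT", "5'"))
        with pytest.raises(it.AssemblyError, match="incompatible"):
            it.gga_assemble([a, b])

    def test_duplicate_overhang_is_ambiguous(self):
        # overhang pattern A-B-A-B admits two distinct circular arrangements
        def frag(body, left, right):
            return it.DigestFragment(body=body, left_overhang=(left, "5'"),
                                     right_overhang=(right, "5'"))
        frags = [frag("AAAA", "GGAG", "TACT"), frag("CCCC", "TACT", "GGAG"),
                 frag("GGGG", "GGAG", "TACT"), frag("TTTT", "TACT", "GGAG")]
        with pytest.raises(it.AssemblyError, match="ambiguous"):
            it.gga_assemble(frags)

    def test_two_fragment_circle(self):
        a = it.DigestFragment(body="AAAA", left_overhang=("GGAG", "5'"),
                              right_overhang=("TACT", "5'"))
        b = it.DigestFragment(body="CCCC", left_overhang=("TACT", "5'"),
                              right_overhang=("GGAG", "5'"))
        product = it.gga_assemble([a, b])
        assert product.sequence == "GGAGAAAATACTCCCC"
        assert product.topology == "circular"

    def test_invariant_under_fragment_permutation(self):
        frags = [
            it.DigestFragment(body="AAAA", left_overhang=("GGAG", "5'"),
                              right_overhang=("TACT", "5'")),
            it.DigestFragment(body="CCCC", left_overhang=("TACT", "5'"),
                              right_overhang=("AATG", "5'")),
            it.DigestFragment(body="GGGG", left_overhang=("AATG", "5'"),
                              right_overhang=("GGAG", "5'")),
        ]
        p1 = it.gga_assemble(frags)
        p2 = it.gga_assemble([frags[2], frags[0], frags[1]])
        assert circular_equal(p1.sequence, p2.sequence)


class TestCassettes:
    def test_standins_satisfy_topologies(self, cassettes):
        for spec in cassettes.values():
            validate_cassette(spec)

    def test_frt_count_rules(self, cassettes):
        p36 = cassettes["pM36-like"]
        assert sum(f.label == "FRT" for f in p36.features) == 0
        p37 = cassettes["pM37-like-p0"]
        assert sum(f.label == "FRT" for f in p37.features) == 2
        assert sum(f.label == "attP" for f in p37.features) == 2

    def test_wrong_topology_rejected(self, cassettes):
        p36 = cassettes["pM36-like"]
        fake = it.CassetteSpec(name=p36.name, cassette_type="pM37-like", phase=0,
                               sequence=p36.sequence, features=p36.features)
        with pytest.raises(it.MalformedModelError, match="FRT"):
            validate_cassette(fake)

    def test_genbank_round_trip(self, fixture_dir, tmp_path):
        spec = it.load_cassette(fixture_dir / "pM37like_p2.gb")
        it.write_genbank(tmp_path / "again.gb", spec.sequence, spec.features,
                         name=spec.name, topology="linear",
                         description="synthetic stand-in cassette phase=2")
        again = it.load_cassette(tmp_path / "again.gb")
        assert again.sequence == spec.sequence
        assert sorted((f.label, f.start, f.end, f.strand) for f in again.features) \
            == sorted((f.label, f.start, f.end, f.strand) for f in spec.features)
        assert again.phase == 2

    def test_carrier_digest_releases_cassette_with_overhangs(self, cassettes):
        enz = get_enzyme("BbsI")
        spec = cassettes["pM37-like-p1"]
        seq, feats = carrier_for(spec, enz, ("TACT", "AATG"))
        frags = it.typeIIS_digest(seq, "circular", enz, features=feats)
        assert len(frags) == 2
        cass = next(f for f in frags if any(ft.label == "SA" for ft in f.features))
        assert cass.left_overhang[0] == "TACT"
        assert cass.right_overhang[0] == "AATG"
        assert cass.body == spec.sequence


class TestDonor:
    def test_length_accounting_identity(self, gold_bundle):
        b = gold_bundle
        d = b.design
        backbone_body = next(
            f for f in it.typeIIS_digest(d.vector.sequence, "circular", d.enzyme,
                                         features=d.vector.features)
            if any(ft.label == "KanR" for ft in f.features)).body
        expected = (len(backbone_body) + d.arm_left.length + d.arm_right.length
                    + len(d.cassette.sequence) + 4 * 4)
        assert len(b.donor.sequence) == expected

    def test_no_surviving_enzyme_sites(self, gold_bundle):
        from introntrap.enzymes import find_sites
        assert find_sites(gold_bundle.donor.sequence,
                          gold_bundle.design.enzyme) == []

    def test_minus_strand_gene_flips_cassette(self, genome, cassettes):
        bundle = it.run_design(genome, "gMinus", cassettes["pM37-like-p2"])
        sa = [f for f in bundle.donor.features if f.label == "SA"]
        assert sa and sa[0].strand == "-"
        attp = sorted((f for f in bundle.donor.features if f.label == "attP"),
                      key=lambda f: f.start)
        assert {f.strand for f in attp} == {"+", "-"}

    def test_origin_spanning_feature_round_trip(self, tmp_path):
        seq = "ACGT" * 25
        it.write_genbank(tmp_path / "o.gb", seq,
                         [it.Feature("wrap", 90, 110, "+"),
                          it.Feature("plain", 10, 30, "-")],
                         name="origin", topology="circular")
        seq2, feats, topo, _ = it.read_genbank(tmp_path / "o.gb")
        assert seq2 == seq and topo == "circular"
        assert it.Feature("wrap", 90, 110, "+") in feats
        assert it.Feature("plain", 10, 30, "-") in feats
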