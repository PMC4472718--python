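"""Binding-site search, amplicon prediction, probe placement and the
virtual gel, checked against a naive sliding-window oracle and constructed
fixtures."""

import numpy as np
import pytest

from oligoplex.ispcr import (
    AmbiguityError,
    Template,
    find_binding_sites,
    locate_probe,
    predict_amplicons,
    simulate_multiplex,
    virtual_gel,
)
from oligoplex.oligos import Oligo, revcomp
from oligoplex.panel import PrimerPair
from oracles import oracle_find_sites


def _random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


FWD = Oligo("fx_F", "GATTACAGATTACAGATG", "forward")
REV = Oligo("fx_R", "CCTTGAGTGACTGACCAT", "reverse")


def _planted(product_size=140, flank=100, seed=5):
    """Background with FWD at position flank+1 and the reverse site placed
    for an exact product size."""
    rng = np.random.default_rng(seed)
    while True:
        bg = _random_dna(rng, 2 * flank + product_size)
        if FWD.sequence not in bg and revcomp(REV.sequence) not in bg:
            break
    inner = product_size - len(FWD) - len(REV)
    seq = (
        bg[:flank]
        + FWD.sequence
        + bg[flank + len(FWD) : flank + len(FWD) + inner]
        + revcomp(REV.sequence)
        + bg[flank + product_size :]
    )
    return Template("planted", seq)


class TestFindBindingSites:
    def test_planted_site_found_exactly(self):
        tpl = _planted()
        hits = find_binding_sites(FWD, tpl)
        assert len(hits) == 1
        h = hits[0]
        assert (h.strand, h.start, h.mismatches) == ("+", 101, 0)
        assert h.end - h.start + 1 == len(FWD)

    def test_single_substitution_kills_exact_match(self):
        tpl = _planted()
        seq = list(tpl.sequence)
        seq[105] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[105]]
        mutated = Template("mut", "".join(seq))
        assert find_binding_sites(FWD, mutated, max_mismatch=0) == []
        relaxed = find_binding_sites(FWD, mutated, max_mismatch=1)
        assert [h.start for h in relaxed] == [101]

    def test_clamp_blocks_3prime_mismatch(self):
        tpl = _planted()
        seq = list(tpl.sequence)
        pos = 101 + len(FWD) - 2  # penultimate base of the plus-strand site
        seq[pos - 1] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[pos - 1]]
        mutated = Template("mut3", "".join(seq))
        assert find_binding_sites(FWD, mutated, max_mismatch=1, clamp3=3) == []
        assert len(find_binding_sites(FWD, mutated, max_mismatch=1, clamp3=0)) == 1

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_naive_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        tpl = Template("rand", _random_dna(rng, 2000))
        oligo = Oligo("probe18", _random_dna(rng, 18))
        for max_mm, clamp3 in [(0, 3), (1, 3), (2, 0), (3, 2)]:
            got = [
                (h.strand, h.start, h.mismatches)
                for h in find_binding_sites(oligo, tpl, max_mm, clamp3)
            ]
            want = sorted(
                oracle_find_sites(oligo.sequence, tpl.sequence, max_mm, clamp3),
                key=lambda t: (t[1], t[0]),
            )
            assert got == sorted(want, key=lambda t: (t[1], t[0]))

    def test_template_shorter_than_oligo(self):
        assert find_binding_sites(FWD, Template("tiny", "ACGT")) == []


class TestPredictAmplicons:
    def test_planted_product_size(self):
        tpl = _planted(product_size=140)
        amps = predict_amplicons(PrimerPair("fx", FWD, REV), tpl)
        assert [a.length for a in amps] == [140]
        a = amps[0]
        assert a.length == a.reverse_hit.end - a.forward_hit.start + 1
        assert len(a.sequence) == a.length
        assert a.sequence.startswith(FWD.sequence)
        assert a.sequence.endswith(revcomp(REV.sequence))

    def test_orientation_rule(self):
        # reverse site upstream of forward site: no product on a linear template
        seq = revcomp(REV.sequence) + "ACGT" * 10 + FWD.sequence
        tpl = Template("inverted", seq)
        assert predict_amplicons(PrimerPair("fx", FWD, REV), tpl) == []

    def test_circular_wraparound_single_product(self):
        # on a circular template the inverted arrangement yields exactly one
        # wrap-around product, never duplicates from the doubled search
        seq = revcomp(REV.sequence) + "ACGT" * 30 + FWD.sequence + "TTAACCGG"
        tpl = Template("circ", seq, topology="circular")
        amps = predict_amplicons(PrimerPair("fx", FWD, REV), tpl)
        assert len(amps) == 1
        want = 8 + len(FWD) + len(REV)  # fwd tail + origin gap + rev head
        assert amps[0].length == want

    def test_circular_doubling_never_duplicates(self):
        tpl_lin = _planted()
        tpl_circ = Template("c", tpl_lin.sequence, topology="circular")
        lin = predict_amplicons(PrimerPair("fx", FWD, REV), tpl_lin)
        circ = predict_amplicons(PrimerPair("fx", FWD, REV), tpl_circ)
        assert [a.length for a in lin] == [a.length for a in circ]


class TestLocateProbe:
    def _amplicon(self):
        tpl = _planted(product_size=140)
        return predict_amplicons(PrimerPair("fx", FWD, REV), tpl)[0]

    def test_plus_strand_interior_site(self):
        a = self._amplicon()
        probe = Oligo("P", a.sequence[40:65], "probe")
        site = locate_probe(probe, a)
        assert (site.strand, site.start, site.end) == ("+", 41, 65)

    def test_minus_strand_site(self):
        a = self._amplicon()
        probe = Oligo("P", revcomp(a.sequence[40:65]), "probe")
        assert locate_probe(probe, a).strand == "-"

    def test_absent_probe(self):
        a = self._amplicon()
        assert locate_probe(Oligo("P", "G" * 10 + "A" * 10, "probe"), a) is None

    def test_overlap_with_primer_footprint_rejected(self):
        a = self._amplicon()
        probe = Oligo("P", a.sequence[10:35], "probe")  # inside fwd footprint
        assert locate_probe(probe, a, allow_overlap=False) is None
        assert locate_probe(probe, a, allow_overlap=True) is not None

    def test_multiple_interior_sites_ambiguous(self):
        seq = FWD.sequence + "AT" + "CACGTGCACG" + "AT" + "CACGTGCACG" + "AT" + revcomp(REV.sequence)
        tpl = Template("dup", seq)
        a = predict_amplicons(PrimerPair("fx", FWD, REV), tpl)[0]
        with pytest.raises(AmbiguityError):
            locate_probe(Oligo("P", "CACGTGCACG", "probe"), a, allow_overlap=True)


class TestVirtualGel:
    def test_published_endpoint_sizes_all_distinguishable(self):
        rep = virtual_gel([438, 351, 191, 140, 87], min_separation=20)
        assert rep.sizes == [438, 351, 191, 140, 87]
        assert rep.all_distinguishable

    def test_close_pair_flagged(self):
        rep = virtual_gel([100, 105], min_separation=20)
        assert rep.indistinct_pairs == [(105, 100)]

    def test_empty_input(self):
        rep = virtual_gel([])
        assert rep.sizes == [] and rep.all_distinguishable


class TestSimulateMultiplex:
    def test_diagonal_on_planted_fixtures(self, panel, apc_cfg):
        from oligoplex.fixtures import make_planted_template

        templates = [
            make_planted_template(
                a, apc_cfg["genomic_sizes"][a.target], seed=33 + i,
                screen_panel=panel,
            )
            for i, a in enumerate(panel)
        ]
        sm = simulate_multiplex(panel, templates)
        owner = {f"target_{a.target}": a.target for a in panel}
        assert sm.is_diagonal(owner)
        for (pname, tid), amps in sm.entries.items():
            if pname.split(":")[0] == owner[tid]:
                use = pname.split(":")[1]
                want = apc_cfg["genomic_sizes"][owner[tid]][use]
                assert [a.length for a in amps] == [want]
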