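import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from methmark.bisulfite_cobra import (
    ENZYMES,
    Amplicon,
    MethylTemplate,
    TaggedPrimer,
    bisulfite_convert,
    cobra_call,
    digest,
    in_silico_pcr,
    reverse_complement,
)
from methmark.io_formats import ValidationError
from methmark.synthetic_data import simulate_methyl_template

from conftest import THBS1_F, THBS1_R, embed_template


def template_of(sequence, cpg_positions, states):
    return MethylTemplate(
        sequence=sequence,
        cpg_positions=tuple(cpg_positions),
        methyl_states=np.asarray(states, dtype=bool),
    )


class TestBisulfiteConvert:
    def test_non_cpg_cytosines_always_convert(self):
        t = template_of("ACCA", [], np.zeros((1, 0)))
        assert bisulfite_convert(t, 0) == "ATTA"

    def test_cpg_site_survival_logic(self):
        """ACGT with a methylated CpG keeps the restriction site; an
        unmethylated CpG destroys it (ATGT)."""
        t = template_of("ACGT", [2], [[True]])
        assert bisulfite_convert(t, 0) == "ACGT"
        t = template_of("ACGT", [2], [[False]])
        assert bisulfite_convert(t, 0) == "ATGT"

    def test_ccga_converts_to_taqi_site_when_methylated(self):
        """Genomic CCGA: the outer C converts, the methylated CpG C is
        protected, yielding the TaqI site TCGA."""
        t = template_of("CCGA", [2], [[True]])
        assert bisulfite_convert(t, 0) == "TCGA"
        t = template_of("CCGA", [2], [[False]])
        assert bisulfite_convert(t, 0) == "TTGA"

    def test_non_acgt_character_rejected(self):
        with pytest.raises(ValidationError):
            template_of("ACNGT", [], np.zeros((1, 0)))

    @given(st.integers(0, 2**32 - 1))
    def test_length_preserved_and_agt_fixed_points(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=60))
        cpgs = [i + 1 for i in range(59) if seq[i : i + 2] == "CG"]
        states = rng.random((1, len(cpgs))) < 0.5
        t = template_of(seq, cpgs, states)
        conv = bisulfite_convert(t, 0)
        assert len(conv) == len(seq)
        for a, b in zip(seq, conv):
            if a in "AGT":
                assert b == a
            else:
                assert b in "CT"
        # C survives exactly at methylated CpG positions
        surviving = {i + 1 for i, b in enumerate(conv) if b == "C"}
        methylated = {p for p, s in zip(cpgs, states[0]) if s}
        assert surviving == methylated


class TestTaggedPrimer:
    def test_tag_and_genomic_split(self):
        assert THBS1_F.tag == "aggaagagag"
        assert THBS1_F.genomic == "GGAGAGAGGAGTTTAGATTGGTTTT"
        assert THBS1_R.tag == "cagtaatacgactcactatagggagaaggct"
        assert THBS1_F.tag + THBS1_F.genomic == THBS1_F.sequence

    def test_short_genomic_part_rejected(self):
        with pytest.raises(ValidationError):
            TaggedPrimer("bad", "aggaagagagGGAGA")

    def test_interleaved_case_rejected(self):
        with pytest.raises(ValidationError):
            TaggedPrimer("bad", "aggaAGGAGAGAGGAGTTTAGAttGGG")


class TestInSilicoPCR:
    def test_single_amplicon_with_expected_length(self):
        middle = "TTACGTTATTTGATTTAGGATT"
        seq, offset = embed_template(middle)
        t = simulate_methyl_template(
            len(seq), [offset + 4], {offset + 4: 1.0}, n_molecules=3, seed=0, sequence=seq
        )
        amps = in_silico_pcr(t, THBS1_F, THBS1_R)
        assert len(amps) == 3
        expected_len = len(seq) + len(THBS1_F.tag) + len(THBS1_R.tag)
        assert all(len(a.sequence) == expected_len for a in amps)
        assert amps[0].covered_cpgs == (offset + 4,)

    def test_no_match_yields_empty_set(self):
        t = simulate_methyl_template(120, [60], {60: 1.0}, n_molecules=2, seed=1)
        assert in_silico_pcr(t, THBS1_F, THBS1_R) == []

    def test_duplicated_forward_site_is_ambiguous(self):
        middle = "TT" + THBS1_F.genomic + "TT"
        seq, _ = embed_template(middle)
        t = template_of(seq, [], np.zeros((1, 0)))
        with pytest.raises(ValidationError, match="ambiguous"):
            in_silico_pcr(t, THBS1_F, THBS1_R)


class TestDigest:
    def _amplify(self, fraction, n, seed=0):
        middle = "TTACGTTATTTGATTTAGGATT"
        seq, offset = embed_template(middle)
        site = offset + 4
        t = simulate_methyl_template(
            len(seq), [site], {site: fraction}, n_molecules=n, seed=seed, sequence=seq
        )
        return in_silico_pcr(t, THBS1_F, THBS1_R), site

    def test_full_controls_cut_exactly(self):
        """100% methylated control: every molecule cut; 0%: none."""
        for fraction, expected in ((1.0, 1.0), (0.0, 0.0)):
            amps, site = self._amplify(fraction, 500)
            res = digest(amps, ENZYMES["HpyCH4IV"])
            assert res.site_cut_fraction[site] == expected

    def test_half_control_within_binomial_bounds(self):
        """50% control at N=10,000: cut count within the binomial 99%
        interval [4871, 5129]."""
        amps, site = self._amplify(0.5, 10000, seed=13)
        res = digest(amps, ENZYMES["HpyCH4IV"])
        lo, hi = stats.binom.interval(0.99, 10000, 0.5)
        assert lo / 10000 <= res.site_cut_fraction[site] <= hi / 10000

    def test_fragments_sum_to_product_length(self):
        amps, _ = self._amplify(0.5, 200)
        res = digest(amps, ENZYMES["HpyCH4IV"])
        for amp, frags in zip(amps, res.fragments):
            assert sum(frags) == len(amp.sequence)

    def test_two_preserved_sites_give_three_fragments(self):
        middle = "TTACGTTATTTTACGTTATTTT"
        seq, offset = embed_template(middle)
        sites = [offset + 4, offset + 14]
        t = simulate_methyl_template(
            len(seq), sites, {s: 1.0 for s in sites}, n_molecules=1, seed=0, sequence=seq
        )
        amps = in_silico_pcr(t, THBS1_F, THBS1_R)
        res = digest(amps, ENZYMES["HpyCH4IV"])
        assert len(res.fragments[0]) == 3
        assert sum(res.fragments[0]) == len(amps[0].sequence)

    def test_exhaustive_site_oracle(self):
        """For every methylation state of a 6-CpG template, HpyCH4IV cuts at
        the assayed ACGT-context CpG iff that CpG is methylated."""
        spacer = "TTATTGATT"
        # CpG contexts: the assayed site in ACGT, the others in TTCGTT
        segments = ["TACGTT"] + ["TTCGTT"] * 5
        middle = spacer + spacer.join(segments) + spacer
        seq, offset = embed_template(middle)
        cpgs = []
        pos = offset + len(spacer)
        for seg in segments:
            cpgs.append(pos + seg.index("CG") + 1)
            pos += len(seg) + len(spacer)
        assayed = cpgs[0]
        assert seq[assayed - 2 : assayed + 2] == "ACGT"
        states = np.array(list(itertools.product([False, True], repeat=6)))
        t = template_of(seq, cpgs, states)
        amps = in_silico_pcr(t, THBS1_F, THBS1_R)
        assert len(amps) == 64
        for i, amp in enumerate(amps):
            res = digest([amp], ENZYMES["HpyCH4IV"])
            cut = res.site_cut_fraction[assayed] == 1.0
            assert cut == bool(states[i][0]), f"state {states[i]}"

    def test_taqi_site_from_methylated_ccga(self):
        middle = "TTCCGATATTTGATTTAGGATT"
        seq, offset = embed_template(middle)
        site = offset + 4  # the C of the CpG inside CCGA
        assert seq[site - 2 : site + 2] == "CCGA"
        for methylated, expect_cut in ((True, 1.0), (False, 0.0)):
            t = template_of(seq, [site], [[methylated]])
            amps = in_silico_pcr(t, THBS1_F, THBS1_R)
            res = digest(amps, ENZYMES["TaqI"])
            assert res.site_cut_fraction[site] == expect_cut


class TestCobraCall:
    def test_extreme_fractions(self):
        middle = "TTACGTTATTTGATTTAGGATT"
        seq, offset = embed_template(middle)
        site = offset + 4
        for fraction, expected in ((1.0, "hypermethylated"), (0.0, "unmethylated")):
            t = simulate_methyl_template(
                len(seq), [site], {site: fraction}, n_molecules=100, seed=0, sequence=seq
            )
            res = digest(in_silico_pcr(t, THBS1_F, THBS1_R), ENZYMES["HpyCH4IV"])
            assert cobra_call(res, site) == expected

    def test_site_outside_amplicon_rejected(self):
        middle = "TTACGTTATTTGATTTAGGATT"
        seq, offset = embed_template(middle)
        site = offset + 4
        t = simulate_methyl_template(
            len(seq), [site], {site: 1.0}, n_molecules=10, seed=0, sequence=seq
        )
        res = digest(in_silico_pcr(t, THBS1_F, THBS1_R), ENZYMES["HpyCH4IV"])
        with pytest.raises(ValidationError):
            cobra_call(res, 99999)

    def test_cohort_pattern_marker_positive_vs_negative(self):
        """Six marker-positive samples (site fraction 0.9) all call
        hypermethylated; six marker-negative samples (0.05) all call
        unmethylated — the per-case binary assay pattern."""
        middle = "TTACGTTATTTGATTTAGGATT"
        seq, offset = embed_template(middle)
        site = offset + 4
        calls = {}
        for group, fraction in (("pos", 0.9), ("neg", 0.05)):
            for j in range(6):
                t = simulate_methyl_template(
                    len(seq), [site], {site: fraction},
                    n_molecules=2000, seed=100 + j + (0 if group == "pos" else 50),
                    sequence=seq,
                )
                res = digest(in_silico_pcr(t, THBS1_F, THBS1_R), ENZYMES["HpyCH4IV"])
                calls[(group, j)] = cobra_call(res, site)
        assert all(c == "hypermethylated" for (g, _), c in calls.items() if g == "pos")
        assert all(c == "unmethylated" for (g, _), c in calls.items() if g == "neg")
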