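"""variant_calling: pileup parsing, filter cascade, artefact flagging."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.proportion import proportion_confint

from mitovar.calling import (ALLELES, CallingThresholds, binomial_interval,
                             call_constitutional, call_somatic,
                             classify_zygosity, depth_of,
                             flag_linked_artefacts, parse_pileup,
                             PileupError, read_count_table,
                             write_count_table)
from mitovar.simulate import SimulationConfig, counts_to_pileup, simulate_pair

from conftest import make_sites, ref_site


# ---------------------------------------------------------------------------
# Brute-force oracle for the filter cascade
# ---------------------------------------------------------------------------

def brute_constitutional(sites, t):
    """Independent scalar application of the five filter predicates."""
    calls = set()
    for rec in sites.itertuples():
        depth = sum(getattr(rec, f"{a}_{s}")
                    for a in ALLELES for s in ("fwd", "rev"))
        for alt in ALLELES:
            if alt == rec.ref:
                continue
            fwd = getattr(rec, f"{alt}_fwd")
            rev = getattr(rec, f"{alt}_rev")
            vac = fwd + rev
            if depth < t.min_depth:
                continue
            if Fraction(vac, depth) < Fraction(str(t.min_vaf)) if depth \
                    else True:
                continue
            if vac < t.min_vac:
                continue
            if fwd < t.min_per_strand or rev < t.min_per_strand:
                continue
            lower, _ = binomial_interval(vac, depth, t.ci_confidence)
            if not lower > 0:
                continue
            calls.add((rec.pos, alt, vac, depth, fwd, rev))
    return calls


def brute_somatic(tumour, normal, t, normalize=True):
    """Scalar somatic predicates on top of the tumour-side cascade."""
    tumour_pass = brute_constitutional(tumour, t)
    by_pos = {int(r.pos): r for r in normal.itertuples()}
    calls = set()
    for pos, alt, vac, depth, fwd, rev in tumour_pass:
        nrec = by_pos.get(int(pos))
        if nrec is None:
            continue
        n_depth = sum(getattr(nrec, f"{a}_{s}")
                      for a in ALLELES for s in ("fwd", "rev"))
        if n_depth < t.min_depth:
            continue
        n_vac = getattr(nrec, f"{alt}_fwd") + getattr(nrec, f"{alt}_rev")
        n_vaf = Fraction(n_vac, n_depth)
        if normalize:
            if Fraction(vac) - n_vaf * depth < t.somatic_min_vac_diff:
                continue
        else:
            if vac - n_vac < t.somatic_min_vac_diff:
                continue
        if Fraction(vac, depth) - n_vaf < Fraction(str(t.somatic_min_vaf_diff)):
            continue
        lower, upper = binomial_interval(vac, depth, t.ci_confidence)
        if lower <= float(n_vaf) <= upper:
            continue
        calls.add((pos, alt, vac, depth, fwd, rev))
    return calls


def random_sites(rng, n, sample_id="S1", max_depth=3000):
    """Random count tables with a mixture of pure and variant sites."""
    rows = []
    for i in range(n):
        ref = ALLELES[rng.integers(4)]
        depth = int(rng.integers(20, max_depth))
        row = {"pos": i + 1, "ref": ref}
        # up to two alt alleles with a wide VAF range, including
        # threshold-straddling values
        remaining = depth
        for alt in rng.permutation([a for a in ALLELES if a != ref])[
                :rng.integers(0, 3)]:
            vac = int(min(remaining, rng.integers(0, max(depth // 3, 2))))
            fwd = int(rng.binomial(vac, 0.5))
            row[f"{alt}_fwd"] = fwd
            row[f"{alt}_rev"] = vac - fwd
            remaining -= vac
        row[f"{ref}_fwd"] = remaining - remaining // 2
        row[f"{ref}_rev"] = remaining // 2
        rows.append(row)
    return make_sites(rows, sample_id=sample_id)


def calls_as_set(calls):
    return {(int(r.pos), r.alt, int(r.vac), int(r.depth),
             int(r.fwd_vac), int(r.rev_vac)) for r in calls.itertuples()}


# ---------------------------------------------------------------------------
# Pileup parsing
# ---------------------------------------------------------------------------

class TestParsePileup:
    def parse_one(self, bases, quals, ref="A", min_baq=20):
        line = f"chrM\t100\t{ref}\t{len(quals)}\t{bases}\t{quals}"
        return parse_pileup([line], min_baq=min_baq)

    def test_all_reference(self):
        df = self.parse_one("..,,", "IIII")
        assert df.loc[0, "A_fwd"] == 2 and df.loc[0, "A_rev"] == 2
        assert depth_of(df)[0] == 4

    def test_low_baq_and_n_dropped(self):
        # 7 base symbols: . $ . , G g N ; one G below min_baq; N dropped
        df = self.parse_one(".$.,GgN", "II" + "I" + "!" + "II")
        # quals map to: '.'(40) '.'(40) ','(40) 'G'(0,dropped) 'g'(40) 'N'(40)
        assert df.loc[0, "A_fwd"] == 2
        assert df.loc[0, "A_rev"] == 1
        assert df.loc[0, "G_fwd"] == 0  # the forward G was below min_baq
        assert df.loc[0, "G_rev"] == 1
        assert depth_of(df)[0] == 4

    def test_read_start_consumed(self):
        df = self.parse_one("^].", "I")
        assert df.loc[0, "A_fwd"] == 1
        assert depth_of(df)[0] == 1

    def test_indel_runs_skipped(self):
        df = self.parse_one(".+2AC.,-1t,", "IIII")
        assert df.loc[0, "A_fwd"] == 2 and df.loc[0, "A_rev"] == 2
        assert depth_of(df)[0] == 4

    def test_deletion_placeholder_excluded(self):
        df = self.parse_one(".*.", "III")
        assert depth_of(df)[0] == 2

    def test_length_mismatch_names_line(self):
        with pytest.raises(PileupError, match="line 1"):
            self.parse_one("...", "II")
        with pytest.raises(PileupError, match="line 1"):
            self.parse_one("..", "III")

    def test_unexpected_symbol(self):
        with pytest.raises(PileupError, match="line 1"):
            self.parse_one(".Z.", "III")

    def test_mass_conservation_random(self, rng):
        """depth equals surviving base symbols on random pileups."""
        for _ in range(20):
            n = int(rng.integers(1, 60))
            symbols, quals = [], []
            survivors = 0
            ref = "C"
            for _ in range(n):
                c = rng.choice(list(".,GgTtNn*"))
                q = int(rng.integers(0, 41))
                symbols.append(c)
                quals.append(chr(q + 33))
                if c not in "Nn*" and q >= 20:
                    survivors += 1
            df = self.parse_one("".join(symbols), "".join(quals), ref=ref)
            assert depth_of(df)[0] == survivors

    def test_round_trip_with_simulator(self):
        config = SimulationConfig(seed=5, mean_depth=150)
        pair = simulate_pair(config, 0)
        counts = pair.normal_counts.head(200)
        text = counts_to_pileup(counts)
        parsed = parse_pileup(text.splitlines(),
                              sample_id=counts["sample_id"].iloc[0])
        pd.testing.assert_frame_equal(
            parsed.reset_index(drop=True),
            counts.reset_index(drop=True).astype(parsed.dtypes))


# ---------------------------------------------------------------------------
# Clopper-Pearson interval
# ---------------------------------------------------------------------------

class TestBinomialInterval:
    def test_zero_count_lower_zero(self):
        lower, upper = binomial_interval(0, 2000, 0.99999)
        assert lower == 0.0 and 0 < upper < 1

    def test_full_count_upper_one(self):
        lower, upper = binomial_interval(2000, 2000, 0.99999)
        assert upper == 1.0 and 0 < lower < 1

    def test_lower_positive(self):
        lower, _ = binomial_interval(10, 100, 0.99999)
        assert lower > 0

    def test_errors(self):
        with pytest.raises(ValueError):
            binomial_interval(1, 0)
        with pytest.raises(ValueError):
            binomial_interval(5, 4)
        with pytest.raises(ValueError):
            binomial_interval(-1, 4)

    def test_statsmodels_oracle(self, rng):
        for _ in range(50):
            depth = int(rng.integers(1, 5000))
            count = int(rng.integers(0, depth + 1))
            conf = float(rng.choice([0.95, 0.99, 0.99999]))
            lo, hi = binomial_interval(count, depth, conf)
            ref_lo, ref_hi = proportion_confint(count, depth,
                                                alpha=1 - conf,
                                                method="beta")
            assert lo == pytest.approx(ref_lo, abs=1e-12)
            assert hi == pytest.approx(ref_hi, abs=1e-12)


# ---------------------------------------------------------------------------
# Zygosity
# ---------------------------------------------------------------------------

class TestZygosity:
    @pytest.mark.parametrize("vaf,expected", [
        (0.05, "heteroplasmy"), (0.995, "homoplasmy"),
        (0.98, "heteroplasmy"), (0.02, "heteroplasmy"),
        (0.019, "homoplasmy"), (1.0, "homoplasmy"), (0.5, "heteroplasmy"),
    ])
    def test_band(self, vaf, expected):
        assert classify_zygosity(vaf) == expected


# ---------------------------------------------------------------------------
# Constitutional calling
# ---------------------------------------------------------------------------

class TestCallConstitutional:
    def test_example_called(self):
        sites = make_sites([ref_site(100, "A", 2000, "G", 25, 25)])
        calls = call_constitutional(sites)
        assert len(calls) == 1
        rec = calls.iloc[0]
        assert rec.alt == "G" and rec.vac == 50
        assert rec.vaf == pytest.approx(0.025)
        assert rec.zygosity == "heteroplasmy"
        assert rec.origin == "constitutional"

    def test_strand_filter_rejects(self):
        sites = make_sites([ref_site(100, "A", 2000, "G", 46, 4)])
        assert call_constitutional(sites).empty

    def test_depth_filter_rejects(self):
        sites = make_sites([ref_site(100, "A", 90, "G", 15, 15)])
        assert call_constitutional(sites).empty

    def test_exact_vaf_boundary_called(self):
        # vac 40 / depth 2000 is exactly 0.02: must pass by exact
        # rational comparison, never float rounding
        sites = make_sites([ref_site(100, "A", 2000, "G", 20, 20)])
        assert len(call_constitutional(sites)) == 1
        sites = make_sites([ref_site(100, "A", 2000, "G", 20, 19)])
        assert call_constitutional(sites).empty  # 39/2000 < 0.02

    def test_vac_boundary(self):
        sites = make_sites([ref_site(100, "A", 400, "G", 5, 5)])
        assert len(call_constitutional(sites)) == 1  # vac=10, vaf=0.025
        sites = make_sites([ref_site(100, "A", 400, "G", 5, 4)])
        assert call_constitutional(sites).empty

    def test_multiallelic_independent(self):
        row = ref_site(100, "A", 2000)
        row.update(G_fwd=30, G_rev=30, T_fwd=25, T_rev=25)
        row["A_fwd"] -= 55
        row["A_rev"] -= 55
        calls = call_constitutional(make_sites([row]))
        assert sorted(calls["alt"]) == ["G", "T"]
        assert (calls["depth"] == 2000).all()

    def test_empty_input(self):
        assert call_constitutional(make_sites([])).empty

    def test_brute_force_oracle(self, rng):
        sites = random_sites(rng, 200)
        for _ in range(5):
            t = CallingThresholds(
                min_depth=int(rng.integers(20, 300)),
                min_vaf=float(rng.choice([0.01, 0.02, 0.05])),
                min_vac=int(rng.integers(2, 30)),
                ci_confidence=float(rng.choice([0.95, 0.99999])),
                min_per_strand=int(rng.integers(0, 10)))
            assert calls_as_set(call_constitutional(sites, t)) == \
                brute_constitutional(sites, t)

    def test_monotonicity(self, rng):
        sites = random_sites(rng, 300)
        base = CallingThresholds()
        base_calls = calls_as_set(call_constitutional(sites, base))
        for kwargs in ({"min_depth": 500}, {"min_vaf": 0.05},
                       {"min_vac": 20}, {"min_per_strand": 10},
                       {"ci_confidence": 0.999999}):
            raised = calls_as_set(
                call_constitutional(sites, base.with_overrides(**kwargs)))
            assert raised <= base_calls


# ---------------------------------------------------------------------------
# Somatic calling
# ---------------------------------------------------------------------------

class TestCallSomatic:
    def test_example_somatic(self):
        tumour = make_sites([ref_site(100, "A", 2000, "G", 25, 25)], "T1")
        normal = make_sites([ref_site(100, "A", 2000)], "N1")
        calls = call_somatic(tumour, normal)
        assert len(calls) == 1
        assert calls.iloc[0].origin == "somatic"
        assert calls.iloc[0].tissue == "tumour"

    def test_small_vaf_difference_rejected(self):
        tumour = make_sites([ref_site(100, "A", 2000, "G", 500, 500)], "T1")
        normal = make_sites([ref_site(100, "A", 2000, "G", 490, 490)], "N1")
        assert call_somatic(tumour, normal).empty  # 0.50 vs 0.49

    def test_low_vac_rejected(self):
        tumour = make_sites([ref_site(100, "A", 300, "G", 5, 4)], "T1")
        normal = make_sites([ref_site(100, "A", 300)], "N1")
        assert call_somatic(tumour, normal).empty

    def test_unmatched_position_warns_and_skips(self):
        tumour = make_sites([ref_site(100, "A", 2000, "G", 25, 25)], "T1")
        normal = make_sites([ref_site(999, "A", 2000)], "N1")
        with pytest.warns(UserWarning, match="no.*matched normal"):
            assert call_somatic(tumour, normal).empty

    def test_normal_depth_required(self):
        tumour = make_sites([ref_site(100, "A", 2000, "G", 25, 25)], "T1")
        normal = make_sites([ref_site(100, "A", 90)], "N1")
        assert call_somatic(tumour, normal).empty

    def test_normalized_vs_raw_vac_diff(self):
        # tumour depth 4000 vac 30; normal depth 400 vac 12 (vaf 0.03)
        # raw diff 30-12=18 >= 10 passes; normalized 30-0.03*4000=-90 fails
        tumour = make_sites([ref_site(100, "A", 4000, "G", 15, 15)], "T1")
        normal = make_sites([ref_site(100, "A", 400, "G", 6, 6)], "N1")
        assert call_somatic(tumour, normal, normalize_vac_diff=True).empty
        raw = call_somatic(tumour, normal, normalize_vac_diff=False)
        # still rejected: VAF difference 0.0075-0.03 < 0.02 -- tighten
        assert raw.empty
        # now a case where only normalization matters: tumour vaf 0.05
        tumour = make_sites([ref_site(100, "A", 4000, "G", 100, 100)], "T1")
        normal = make_sites([ref_site(100, "A", 8000, "G", 80, 80)], "N1")
        # raw diff 200-160=40 passes; normalized 200-0.02*4000=120 passes
        # both pass here; check the asymmetric case: normal deeper with
        # proportionally more variant reads
        normal = make_sites([ref_site(100, "A", 12000, "G", 180, 180)], "N1")
        # normal vaf 0.03; tumour vaf 0.05; vaf diff exactly 0.02 passes;
        # normalized vac diff 200 - 0.03*4000 = 80 passes;
        # raw diff 200-360 = -160 fails
        assert len(call_somatic(tumour, normal,
                                normalize_vac_diff=True)) == 1
        assert call_somatic(tumour, normal,
                            normalize_vac_diff=False).empty

    def test_output_invariants(self, rng):
        tumour = random_sites(rng, 300, "T1")
        normal = random_sites(rng, 300, "N1")
        t = CallingThresholds()
        calls = call_somatic(tumour, normal, t)
        const = calls_as_set(call_constitutional(tumour, t))
        n_by_pos = {int(r.pos): r for r in normal.itertuples()}
        for rec in calls.itertuples():
            key = (int(rec.pos), rec.alt, int(rec.vac), int(rec.depth),
                   int(rec.fwd_vac), int(rec.rev_vac))
            assert key in const  # tumour-side cascade holds
            nrec = n_by_pos[int(rec.pos)]
            n_depth = sum(getattr(nrec, f"{a}_{s}")
                          for a in ALLELES for s in ("fwd", "rev"))
            n_vac = (getattr(nrec, f"{rec.alt}_fwd")
                     + getattr(nrec, f"{rec.alt}_rev"))
            assert (Fraction(int(rec.vac), int(rec.depth))
                    - Fraction(n_vac, n_depth)) >= Fraction(1, 50)

    def test_brute_force_oracle(self, rng):
        tumour = random_sites(rng, 200, "T1")
        normal = random_sites(rng, 200, "N1")
        for normalize in (True, False):
            for _ in range(3):
                t = CallingThresholds(
                    min_depth=int(rng.integers(20, 200)),
                    min_vaf=float(rng.choice([0.01, 0.02])),
                    min_vac=int(rng.integers(2, 20)),
                    somatic_min_vac_diff=int(rng.integers(2, 20)),
                    somatic_min_vaf_diff=float(rng.choice([0.01, 0.02])))
                got = calls_as_set(call_somatic(tumour, normal, t,
                                                normalize_vac_diff=normalize))
                assert got == brute_somatic(tumour, normal, t, normalize)


# ---------------------------------------------------------------------------
# Count-table IO
# ---------------------------------------------------------------------------

class TestCountTableIO:
    def test_round_trip(self, tmp_path, rng):
        sites = random_sites(rng, 50)
        path = tmp_path / "counts.tsv"
        write_count_table(sites, path)
        again = read_count_table(path)
        pd.testing.assert_frame_equal(again, sites.astype(again.dtypes))

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("sample_id\tpos\nS\t1\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_count_table(path)


# ---------------------------------------------------------------------------
# Linked artefacts
# ---------------------------------------------------------------------------

def obs_frame(rows):
    return pd.DataFrame(rows, columns=["read_id", "pos", "allele"])


class TestLinkedArtefacts:
    PAIR = [((100, "T"), (150, "A"))]

    def test_perfect_linkage_flagged(self):
        rows = [{"read_id": f"r{i}", "pos": p, "allele": a}
                for i in range(100) for p, a in ((100, "T"), (150, "A"))]
        out = flag_linked_artefacts(obs_frame(rows), self.PAIR)
        assert out.iloc[0].flagged and out.iloc[0].fraction == 1.0

    def test_disjoint_not_flagged(self):
        rows = []
        for i in range(50):
            rows.append({"read_id": f"r{i}", "pos": 100, "allele": "T"})
            rows.append({"read_id": f"r{i}", "pos": 150, "allele": "C"})
        for i in range(50, 100):
            rows.append({"read_id": f"r{i}", "pos": 100, "allele": "C"})
            rows.append({"read_id": f"r{i}", "pos": 150, "allele": "A"})
        out = flag_linked_artefacts(obs_frame(rows), self.PAIR)
        assert not out.iloc[0].flagged and out.iloc[0].fraction == 0.0

    def test_95_of_100_flagged_at_default(self):
        rows = []
        for i in range(95):  # both alts
            rows.append({"read_id": f"r{i}", "pos": 100, "allele": "T"})
            rows.append({"read_id": f"r{i}", "pos": 150, "allele": "A"})
        for i in range(95, 100):  # first alt only
            rows.append({"read_id": f"r{i}", "pos": 100, "allele": "T"})
            rows.append({"read_id": f"r{i}", "pos": 150, "allele": "C"})
        out = flag_linked_artefacts(obs_frame(rows), self.PAIR)
        assert out.iloc[0].fraction == pytest.approx(0.95)
        assert out.iloc[0].flagged

    def test_partner_alone_blocks_flag(self):
        rows = []
        for i in range(99):
            rows.append({"read_id": f"r{i}", "pos": 100, "allele": "T"})
            rows.append({"read_id": f"r{i}", "pos": 150, "allele": "A"})
        # one read carries the partner without the first allele
        rows.append({"read_id": "solo", "pos": 100, "allele": "C"})
        rows.append({"read_id": "solo", "pos": 150, "allele": "A"})
        out = flag_linked_artefacts(obs_frame(rows), self.PAIR)
        assert not out.iloc[0].flagged
        assert out.iloc[0].fraction == pytest.approx(0.99)

    def test_untestable_without_covering_reads(self):
        rows = [{"read_id": "r1", "pos": 100, "allele": "T"},
                {"read_id": "r2", "pos": 150, "allele": "A"}]
        out = flag_linked_artefacts(obs_frame(rows), self.PAIR)
        assert out.iloc[0].untestable and not out.iloc[0].flagged
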