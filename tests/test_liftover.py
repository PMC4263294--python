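import numpy as np
import pytest

from conftest import write_lines
from oracles import oracle_map_interval, random_chain, walk_chain_bases
from oxomap.errors import ParseError, ValidationError
from oxomap.io_formats import IntervalValue
from oxomap.liftover import (
    ChainSet,
    LiftoverParams,
    map_interval,
    map_profile,
    parse_chain,
    parse_chain_text,
)

IDENTITY_CHAIN = """chain 1000 chr1 1000 + 0 1000 chr1 1000 + 0 1000 1
1000
"""

TOY_CHAIN = """chain 900 chrT 250 + 0 250 chrQ 200 + 0 200 1
100 50 0
100
"""


class TestParseChain:
    def test_identity_chain(self):
        cs = parse_chain_text(IDENTITY_CHAIN)
        assert len(cs) == 1
        chain = cs.chains[0]
        assert chain.t_end - chain.t_start == 1000
        assert chain.sizes.tolist() == [1000]

    def test_span_mismatch_cites_chain_id(self):
        bad = "chain 1 chr1 1000 + 0 1000 chr1 1000 + 0 999 7\n1000\n"
        with pytest.raises(ParseError, match="chain 7"):
            parse_chain_text(bad)

    def test_three_chain_file_scores_preserved(self, tmp_path):
        rng = np.random.default_rng(5)
        chains = [random_chain(rng, i + 1) for i in range(3)]
        text = ""
        for c in chains:
            blocks = [
                f"{s} {dt} {dq}" for s, dt, dq in zip(c.sizes[:-1], c.dt[:-1], c.dq[:-1])
            ] + [str(c.sizes[-1])]
            text += (
                f"chain {c.score:g} {c.t_name} {c.t_size} + {c.t_start} {c.t_end} "
                f"{c.q_name} {c.q_size} {c.q_strand} {c.q_start} {c.q_end} {c.chain_id}\n"
                + "\n".join(blocks)
                + "\n\n"
            )
        path = write_lines(tmp_path / "toy.chain", [text])
        cs = parse_chain(path)
        assert len(cs) == 3
        assert sorted(c.score for c in cs.chains) == sorted(c.score for c in chains)

    def test_t_strand_minus_rejected(self):
        bad = "chain 1 chr1 1000 - 0 1000 chr1 1000 + 0 1000 1\n1000\n"
        with pytest.raises(ParseError):
            parse_chain_text(bad)

    def test_block_line_outside_chain_rejected(self):
        with pytest.raises(ParseError):
            parse_chain_text("100 1 1\n")


class TestMapInterval:
    def test_identity_maps_to_itself(self):
        cs = parse_chain_text(IDENTITY_CHAIN)
        res = map_interval("chr1", 17, 523, cs)
        assert res.ok and (res.chrom, res.start, res.end) == ("chr1", 17, 523)

    def test_toy_chain_envelope_and_fraction(self):
        cs = parse_chain_text(TOY_CHAIN)
        res = map_interval("chrT", 0, 250, cs)
        assert res.ok
        assert (res.start, res.end) == (0, 200)
        assert res.mapped_fraction == pytest.approx(0.8)

    def test_interval_in_gap_is_deleted(self):
        cs = parse_chain_text(TOY_CHAIN)
        res = map_interval("chrT", 110, 140, cs)  # inside the dt gap
        assert not res.ok and res.reason == "deleted"

    def test_min_blocks_threshold(self):
        cs = parse_chain_text(TOY_CHAIN)
        # interval [95, 145): 5 aligned of 50 -> fraction 0.1
        res = map_interval("chrT", 95, 145, cs, LiftoverParams(min_blocks=0.1))
        assert res.ok
        res = map_interval("chrT", 95, 145, cs, LiftoverParams(min_blocks=0.2))
        assert not res.ok and res.reason == "partially_deleted"

    def test_ambiguous_two_eligible_chains(self):
        two = IDENTITY_CHAIN + "chain 500 chr1 1000 + 0 1000 chr2 1000 + 0 1000 2\n1000\n"
        cs = parse_chain_text(two)
        res = map_interval("chr1", 0, 100, cs)
        assert not res.ok and res.reason == "ambiguous"

    def test_best_chain_resolves_by_score(self):
        two = IDENTITY_CHAIN + "chain 500 chr1 1000 + 0 1000 chr2 1000 + 0 1000 2\n1000\n"
        cs = parse_chain_text(two)
        res = map_interval("chr1", 0, 100, cs, LiftoverParams(best_chain=True))
        assert res.ok and res.chain_id == 1

    def test_strand_flip_reflection(self):
        minus = "chain 100 chrT 100 + 0 100 chrQ 500 - 0 100 1\n100\n"
        cs = parse_chain_text(minus)
        res = map_interval("chrT", 0, 10, cs)
        # t base 0 -> q-strand pos 0 -> plus strand 499; envelope [490, 500)
        assert res.ok and (res.start, res.end) == (490, 500)

    def test_monotonicity_in_min_blocks(self):
        cs = parse_chain_text(TOY_CHAIN)
        rng = np.random.default_rng(9)
        for _ in range(50):
            s = int(rng.integers(0, 240))
            e = int(rng.integers(s + 1, 251))
            ok_levels = [
                map_interval("chrT", s, e, cs, LiftoverParams(min_blocks=mb)).ok
                for mb in (0.05, 0.3, 0.7, 1.0)
            ]
            # once failing, never succeeds again at stricter thresholds
            for earlier, later in zip(ok_levels, ok_levels[1:]):
                assert earlier or not later

    def test_invalid_interval_rejected(self):
        cs = parse_chain_text(IDENTITY_CHAIN)
        with pytest.raises(ValidationError):
            map_interval("chr1", 10, 10, cs)


class TestPerBaseOracle:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_random_chains_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        chains = ChainSet([random_chain(rng, i + 1) for i in range(int(rng.integers(1, 4)))])
        t_max = max(c.t_end for c in chains.chains)
        for _ in range(100):
            s = int(rng.integers(0, t_max))
            e = int(rng.integers(s + 1, t_max + 20))
            for mb in (0.1, 0.5):
                got = map_interval("chrT", s, e, chains, LiftoverParams(min_blocks=mb))
                label, span = oracle_map_interval("chrT", s, e, chains, mb)
                if label == "mapped":
                    assert got.ok, (s, e, mb)
                    assert (got.chrom, got.start, got.end) == span
                else:
                    assert not got.ok and got.reason == label, (s, e, mb)

    def test_forced_strand_flip_matches_oracle(self):
        rng = np.random.default_rng(99)
        chains = ChainSet([random_chain(rng, 1, q_strand="-")])
        t_max = chains.chains[0].t_end
        for _ in range(100):
            s = int(rng.integers(0, t_max))
            e = int(rng.integers(s + 1, t_max + 10))
            got = map_interval("chrT", s, e, chains, LiftoverParams(min_blocks=0.1))
            label, span = oracle_map_interval("chrT", s, e, chains, 0.1)
            if label == "mapped":
                assert got.ok and (got.chrom, got.start, got.end) == span
            else:
                assert not got.ok and got.reason == label

    def test_walk_covers_all_aligned_bases(self):
        cs = parse_chain_text(TOY_CHAIN)
        bases = list(walk_chain_bases(cs.chains[0]))
        assert len(bases) == 200
        assert bases[0] == (0, 0) and bases[-1] == (249, 199)


class TestMapProfile:
    def test_identity_profile(self):
        cs = parse_chain_text(IDENTITY_CHAIN)
        track = [IntervalValue("chr1", 0, 100, 1.5), IntervalValue("chr1", 100, 300, -2.0)]
        mapped, report = map_profile(track, cs)
        assert mapped == track
        assert report.n_mapped == 2 and not report.failures

    def test_deleted_interval_reported(self):
        cs = parse_chain_text(TOY_CHAIN)
        track = [IntervalValue("chrT", i * 25, i * 25 + 25, float(i)) for i in range(10)]
        mapped, report = map_profile(track, cs)
        # [100,125) and [125,150) are both fully inside the 50 bp gap
        assert report.failures.get("deleted", 0) == 2
        assert report.n_input == report.n_mapped + len(report.unmapped)

    def test_strand_flip_preserves_values_resorts(self):
        minus = "chain 100 chrT 100 + 0 100 chrQ 500 - 0 100 1\n100\n"
        cs = parse_chain_text(minus)
        track = [IntervalValue("chrT", 0, 10, 1.0), IntervalValue("chrT", 50, 60, 2.0)]
        mapped, report = map_profile(track, cs)
        assert [m.value for m in mapped] == [2.0, 1.0]  # order reversed on q
        assert [(m.start, m.end) for m in mapped] == [(440, 450), (490, 500)]

    def test_destination_collision_dropped_and_counted(self):
        # two chains squeezing distinct t intervals onto overlapping q spans
        text = (
            "chain 10 chrT 100 + 0 100 chrQ 100 + 0 100 1\n100\n\n"
            "chain 5 chrT2 100 + 0 100 chrQ 100 + 0 100 2\n100\n"
        )
        cs = parse_chain_text(text)
        track = [IntervalValue("chrT", 0, 50, 1.0), IntervalValue("chrT2", 10, 60, 2.0)]
        mapped, report = map_profile(track, cs)
        assert report.n_mapped == 1 and report.n_collided == 1
        assert mapped[0].value == 1.0  # input order wins
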