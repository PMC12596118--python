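"""CRISPR array detection, filters, and spacer matching."""

import numpy as np
import pytest

from lysismine.crispr import (
    CrisprArray,
    detect_arrays,
    filter_arrays,
    host_range,
    match_spacers,
    subsample_host_range,
)
from lysismine.records import SeqRecord
from lysismine.synth import plant_crispr_link

NT = list("ACGT")


def random_genome(n, seed, gid="h1", source="bacterial"):
    rng = np.random.default_rng(seed)
    return SeqRecord(id=gid, residues="".join(rng.choice(NT, size=n)), alphabet="nt", source=source)


def viral(n, seed, gid="v1"):
    return random_genome(n, seed, gid=gid, source="viral")


class TestDetection:
    def test_planted_array_recovered_with_exact_boundaries(self):
        host = random_genome(20_000, seed=1)
        virus = viral(30_000, seed=2)
        planted, spacers, links = plant_crispr_link(host, virus, n_spacers=3, seed=3)
        arrays = detect_arrays(planted)
        arrays = filter_arrays(arrays)
        assert len(arrays) == 1
        arr = arrays[0]
        assert arr.n_spacers == 3
        # exact boundaries: extracted spacers equal the planted ones
        assert sorted(s for s, _, _ in arr.spacers) == sorted(spacers.values())
        assert len(arr.repeat) == 28

    def test_short_repeat_below_min_not_reported(self):
        rng = np.random.default_rng(4)
        repeat = "".join(rng.choice(NT, size=18))  # < minRL 20
        spacers = ["".join(rng.choice(NT, size=30)) for _ in range(3)]
        array = repeat + "".join(s + repeat for s in spacers)
        bg = "".join(rng.choice(NT, size=3000))
        g = SeqRecord(id="h", residues=bg[:1500] + array + bg[1500:], alphabet="nt")
        assert all(len(a.repeat) >= 20 for a in detect_arrays(g))

    def test_random_genome_clean_after_filter(self):
        g = random_genome(30_000, seed=5)
        assert filter_arrays(detect_arrays(g)) == []


class TestFilters:
    def arr(self, repeat_len, spacer_len, n_spacers):
        rpos = [(i * (repeat_len + spacer_len), i * (repeat_len + spacer_len) + repeat_len)
                for i in range(n_spacers + 1)]
        spacers = [("A" * spacer_len, e, e + spacer_len) for (_, e) in rpos[:-1]]
        return CrisprArray("g", "A" * repeat_len, rpos, spacers)

    def test_good_ratio_retained(self):
        assert len(filter_arrays([self.arr(28, 30, 3)])) == 1

    def test_two_spacers_removed(self):
        assert filter_arrays([self.arr(28, 30, 2)]) == []

    def test_high_ratio_removed(self):
        assert filter_arrays([self.arr(20, 60, 3)]) == []


class TestMatching:
    def test_exact_and_single_mismatch_accepted_two_rejected(self):
        virus = viral(10_000, seed=6)
        proto = virus.residues[2_000:2_030]
        one_mm = "G" + proto[1:] if proto[0] != "G" else "A" + proto[1:]
        two_mm = list(proto)
        two_mm[3] = "A" if proto[3] != "A" else "C"
        two_mm[17] = "A" if proto[17] != "A" else "C"
        spacers = {"s0": proto, "s1": one_mm, "s2": "".join(two_mm)}
        matches = {m.spacer_id: m for m in match_spacers(spacers, [virus])}
        assert matches["s0"].mismatches == 0 and matches["s0"].identity == 1.0
        assert matches["s0"].position == 2_000
        assert matches["s1"].mismatches == 1
        assert matches["s1"].identity == pytest.approx(29 / 30)
        assert "s2" not in matches

    def test_minus_strand_protospacer(self):
        from lysismine.crispr import _revcomp

        virus = viral(8_000, seed=7)
        proto = virus.residues[3_000:3_032]
        matches = match_spacers({"s": _revcomp(proto)}, [virus])
        assert len(matches) == 1
        assert matches[0].strand == "-"
        assert matches[0].position == 3_000

    def test_strand_symmetry(self):
        """Reverse-complementing the viral genome flips strands only."""
        virus = viral(9_000, seed=8)
        spacers = {"s0": virus.residues[1_000:1_030], "s1": virus.residues[5_000:5_030]}
        fwd = {m.spacer_id: m for m in match_spacers(spacers, [virus])}
        rc = {m.spacer_id: m for m in match_spacers(spacers, [virus.reverse_complement()])}
        assert set(fwd) == set(rc)
        for sid in fwd:
            assert fwd[sid].mismatches == rc[sid].mismatches
            assert fwd[sid].strand != rc[sid].strand

    def test_short_spacer_rejected(self):
        with pytest.raises(ValueError):
            match_spacers({"s": "ACGT"}, [viral(1_000, seed=9)])


class TestHostRange:
    def test_distinct_species_counts(self):
        assignments = {"v1": {"A", "B"}, "v2": {"A"}, "v3": set()}
        assert host_range(assignments) == {"v1": 2, "v2": 1, "v3": 0}

    def test_unmatched_virus_reported_zero(self):
        assert host_range({}, all_viruses=["v9"]) == {"v9": 0}

    def test_quota_subsampling(self):
        rng = np.random.default_rng(10)
        species = [f"sp{i}" for i in range(150)]
        taxonomy = {s: "PhylumBig" for s in species}
        small = [f"ss{i}" for i in range(20)]
        taxonomy.update({s: "PhylumSmall" for s in small})
        assignments = {"v": set(species) | set(small)}
        df = subsample_host_range(assignments, taxonomy, phylum_quota=100, reps=5, seed=1)
        # 100 sampled from the big phylum + all 20 of the small one
        assert df.loc[0, "mean_host_range"] == pytest.approx(120.0)

    def test_special_quota_override(self):
        species = [f"sp{i}" for i in range(150)]
        taxonomy = {s: "Pseudomonadota" for s in species}
        assignments = {"v": set(species)}
        df = subsample_host_range(
            assignments, taxonomy, phylum_quota=100,
            special_quotas={"Pseudomonadota": 2000}, reps=3, seed=2,
        )
        # below the special quota: phylum retained entirely
        assert df.loc[0, "mean_host_range"] == pytest.approx(150.0)

    def test_determinism(self):
        species = {f"sp{i}": "P" for i in range(120)}
        assignments = {"v": set(species)}
        a = subsample_host_range(assignments, species, reps=4, seed=3)
        b = subsample_host_range(assignments, species, reps=4, seed=3)
        assert a.equals(b)
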