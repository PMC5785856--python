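"""Allele-balance loading, mode detection and ploidy pattern calls."""

import numpy as np
import pandas as pd
import pytest

from ppscan.errors import PpscanError
from ppscan.ploidyscan import (
    call_ploidy,
    classify_ploidy_pattern,
    compare_gene_sets,
    detect_modes,
    load_het_sites,
)
from ppscan.synthetic_data import HetSimConfig, simulate_het_sites


def _table(rel_alt, depth=60):
    rel = np.asarray(rel_alt, dtype=float)
    alt = np.round(rel * depth).astype(int)
    return pd.DataFrame(
        {
            "scaffold": "s1",
            "pos": np.arange(1, len(rel) + 1),
            "ref_depth": depth - alt,
            "alt_depth": alt,
            "rel_alt": alt / depth,
        }
    )


class TestLoadHetSites:
    def _write(self, tmp_path, rows, header="chrom\tpos\tref_depth\talt_depth\tmq"):
        p = tmp_path / "sites.tsv"
        p.write_text(header + "\n" + "\n".join(rows) + "\n")
        return p

    def test_depth_18_dropped(self, tmp_path):
        p = self._write(tmp_path, ["s1\t1\t9\t9\t60", "s1\t2\t30\t30\t60"])
        df, log = load_het_sites(p)
        assert list(df.pos) == [2]

    def test_depth_just_above_threshold_kept(self, tmp_path):
        # depth must be strictly greater than the threshold
        p = self._write(tmp_path, ["s1\t1\t10\t10\t60", "s1\t2\t11\t10\t60"])
        df, _ = load_het_sites(p)
        assert list(df.pos) == [2]

    def test_mq_35_dropped(self, tmp_path):
        p = self._write(tmp_path, ["s1\t1\t30\t30\t35", "s1\t2\t30\t30\t41"])
        df, log = load_het_sites(p)
        assert list(df.pos) == [2]

    def test_rel_alt_is_alt_over_total(self, tmp_path):
        p = self._write(tmp_path, ["s1\t1\t30\t30\t60"])
        df, _ = load_het_sites(p)
        assert df.rel_alt.iloc[0] == pytest.approx(0.5)

    def test_homozygous_rows_dropped(self, tmp_path):
        p = self._write(tmp_path, ["s1\t1\t60\t0\t60", "s1\t2\t30\t30\t60"])
        df, log = load_het_sites(p)
        assert list(df.pos) == [2]
        assert log["n_dropped_homozygous"] == 1

    def test_missing_columns_named(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("chrom\tpos\tref_depth\n" + "s1\t1\t30\n")
        with pytest.raises(PpscanError, match="alt_depth"):
            load_het_sites(p)

    def test_tsv_without_mq_column_accepted(self, tmp_path):
        p = self._write(tmp_path, ["s1\t1\t30\t30"],
                        header="chrom\tpos\tref_depth\talt_depth")
        df, _ = load_het_sites(p)
        assert len(df) == 1


class TestDetectModes:
    def test_diploid_single_mode_near_half(self):
        df = simulate_het_sites(HetSimConfig(ploidy=2, n_sites=10_000, seed=1))
        modes = detect_modes(df)
        assert len(modes) == 1
        assert modes[0] == pytest.approx(0.5, abs=0.02)

    def test_triploid_two_modes(self):
        df = simulate_het_sites(HetSimConfig(ploidy=3, n_sites=10_000, seed=2))
        modes = detect_modes(df)
        assert len(modes) == 2
        assert modes[0] == pytest.approx(1 / 3, abs=0.02)
        assert modes[1] == pytest.approx(2 / 3, abs=0.02)

    def test_tetraploid_three_modes(self):
        df = simulate_het_sites(HetSimConfig(ploidy=4, n_sites=10_000, seed=3))
        modes = detect_modes(df)
        assert len(modes) == 3
        for m, expect in zip(modes, (0.25, 0.5, 0.75)):
            assert m == pytest.approx(expect, abs=0.02)

    def test_point_mass_yields_single_exact_mode(self):
        df = _table([0.5] * 100)
        assert detect_modes(df) == [0.5]

    def test_too_few_sites_unresolved_not_error(self):
        df = _table([0.5] * 4)
        assert detect_modes(df, min_sites=5) == []
        assert call_ploidy(df, min_sites=5).pattern == "unresolved"

    def test_reflection_symmetry(self):
        """Reflecting rel_alt -> 1-rel_alt maps the mode set onto its
        mirror image (diploid/tetraploid fixed, triploid modes swapped),
        up to one bin: depth-lattice values landing exactly on a bin edge
        fall into different half-open bins after mirroring."""
        for ploidy, seed in ((2, 4), (3, 5), (4, 6)):
            df = simulate_het_sites(HetSimConfig(ploidy=ploidy,
                                                 n_sites=10_000, seed=seed))
            mirrored = df.copy()
            mirrored["rel_alt"] = 1.0 - mirrored["rel_alt"]
            m1 = detect_modes(df)
            m2 = detect_modes(mirrored)
            assert len(m1) == len(m2)
            assert np.allclose(sorted(1.0 - np.array(m1)), m2, atol=0.0201)


class TestClassifyPattern:
    @pytest.mark.parametrize(
        "modes,expect",
        [
            ([0.49], "diploid"),
            ([0.26, 0.51, 0.74], "tetraploid"),
            ([0.40], "unresolved"),
            ([0.33, 0.67], "triploid"),
            ([0.3, 0.7], "triploid"),
            ([], "unresolved"),
            ([0.25, 0.75], "unresolved"),  # central mode absent
        ],
    )
    def test_template_matching(self, modes, expect):
        assert classify_ploidy_pattern(modes) == expect

    def test_pattern_recovery_rate_on_simulated_units(self):
        correct = total = 0
        names = {2: "diploid", 3: "triploid", 4: "tetraploid"}
        for ploidy in (2, 3, 4):
            for unit in range(20):
                df = simulate_het_sites(
                    HetSimConfig(ploidy=ploidy, n_sites=500, depth_mean=60,
                                 seed=1000 * ploidy + unit)
                )
                call = call_ploidy(df, unit=f"u{unit}")
                correct += call.pattern == names[ploidy]
                total += 1
        assert correct / total >= 0.95


class TestCompareGeneSets:
    @staticmethod
    def _sets_table(seed=7):
        rng = np.random.default_rng(seed)
        n = 1000
        frames = []
        coords = {}
        specs = {"T1": 2, "T2": None, "T3": 4}  # T2 = 50/50 mixture
        pos0 = 1
        for name, ploidy in specs.items():
            if ploidy is None:
                half = n // 2
                d2 = simulate_het_sites(HetSimConfig(2, half, 60, seed=int(rng.integers(1 << 30))))
                d4 = simulate_het_sites(HetSimConfig(4, n - half, 60, seed=int(rng.integers(1 << 30))))
                df = pd.concat([d2, d4], ignore_index=True)
            else:
                df = simulate_het_sites(HetSimConfig(ploidy, n, 60, seed=int(rng.integers(1 << 30))))
            df = df.copy()
            df["scaffold"] = "s1"
            df["pos"] = np.arange(pos0, pos0 + len(df))
            coords[name] = [("s1", pos0, pos0 + len(df) - 1)]
            pos0 += len(df) + 10
            frames.append(df)
        return pd.concat(frames, ignore_index=True), coords

    def test_tetraploid_set_has_larger_spread(self):
        table, coords = self._sets_table()
        report = compare_gene_sets(table, coords)
        assert report["mean_spread"]["T3"] > report["mean_spread"]["T1"]
        assert report["pairwise"]["T1_vs_T3"]["p_value"] < 1e-6

    def test_mixture_set_is_intermediate(self):
        table, coords = self._sets_table()
        report = compare_gene_sets(table, coords)
        assert report["spread_order"] == ["T1", "T2", "T3"]

    def test_identical_sets_not_significant(self):
        df = simulate_het_sites(HetSimConfig(2, 1000, 60, seed=8))
        df["scaffold"] = "s1"
        df["pos"] = np.arange(1, len(df) + 1)
        half = len(df) // 2
        coords = {
            "A": [("s1", 1, half)],
            "B": [("s1", half + 1, len(df))],
        }
        report = compare_gene_sets(df, coords)
        assert report["pairwise"]["A_vs_B"]["p_value"] > 0.05

    def test_small_sets_skipped_with_log(self):
        df = simulate_het_sites(HetSimConfig(2, 100, 60, seed=9))
        df["scaffold"] = "s1"
        df["pos"] = np.arange(1, len(df) + 1)
        coords = {"big": [("s1", 1, 100)], "tiny": [("s1", 1, 2)]}
        report = compare_gene_sets(df, coords)
        assert report["skipped_sets"] == ["tiny"]
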