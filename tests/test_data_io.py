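import logging

import numpy as np
import pytest

from refstab.data_io import (CqTable, EfficiencySet, collapse_replicates,
                             complete_case_subset, read_cq_table,
                             read_efficiencies, write_cq_table)
from refstab.errors import InputError
from tests.conftest import make_table, random_table


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text, encoding="utf-8")
    return p


class TestReadLong:
    def test_minimal_long_csv(self, tmp_path):
        p = write(tmp_path, "cq.csv",
                  "sample_id,group,gene,cq\n"
                  "s1,liver,ACTB,20.1\ns1,liver,GAPDH,19.8\n"
                  "s2,heart,ACTB,20.5\ns2,heart,GAPDH,20.0\n")
        t = read_cq_table(p, layout="long")
        assert t.genes == ["ACTB", "GAPDH"]
        assert t.samples == ["s1", "s2"]
        assert set(t.group_of.values()) == {"liver", "heart"}
        np.testing.assert_allclose(t.cq, [[20.1, 20.5], [19.8, 20.0]])

    def test_tsv_accepted(self, tmp_path):
        p = write(tmp_path, "cq.tsv",
                  "sample_id\tgene\tcq\ns1\tA\t20\ns1\tB\t21\n")
        t = read_cq_table(p, layout="long")
        assert t.n_genes == 2 and t.n_samples == 1

    def test_duplicate_triple_hard_error(self, tmp_path):
        p = write(tmp_path, "cq.csv",
                  "sample_id,gene,cq\ns1,ACTB,20.1\ns1,ACTB,20.3\n")
        with pytest.raises(InputError, match="ACTB"):
            read_cq_table(p, layout="long")

    def test_duplicate_allowed_with_replicates(self, tmp_path):
        p = write(tmp_path, "cq.csv",
                  "sample_id,replicate,gene,cq\n"
                  "s1,r1,ACTB,20.1\ns1,r2,ACTB,20.3\n")
        t = read_cq_table(p, layout="long")
        assert t.n_samples == 2
        assert t.replicate_of is not None

    def test_missing_mandatory_column(self, tmp_path):
        p = write(tmp_path, "cq.csv", "sample_id,gene\ns1,ACTB\n")
        with pytest.raises(InputError, match="cq"):
            read_cq_table(p, layout="long")

    def test_unparseable_cq_becomes_missing(self, tmp_path, caplog):
        p = write(tmp_path, "cq.csv",
                  "sample_id,gene,cq\ns1,A,oops\ns1,B,20\ns2,A,21\ns2,B,22\n")
        with caplog.at_level(logging.WARNING):
            t = read_cq_table(p, layout="long")
        assert np.isnan(t.cq[0, 0])
        assert "unparseable" in caplog.text

    def test_undetermined_is_missing_without_warning(self, tmp_path, caplog):
        p = write(tmp_path, "cq.csv",
                  "sample_id,gene,cq\ns1,A,Undetermined\ns2,A,21\n")
        with caplog.at_level(logging.WARNING):
            t = read_cq_table(p, layout="long")
        assert np.isnan(t.cq[0, 0])
        assert "unparseable" not in caplog.text

    def test_first_seen_order_preserved(self, tmp_path):
        p = write(tmp_path, "cq.csv",
                  "sample_id,gene,cq\nsB,Z,20\nsA,Y,21\nsB,Y,22\nsA,Z,23\n")
        t = read_cq_table(p, layout="long")
        assert t.genes == ["Z", "Y"]
        assert t.samples == ["sB", "sA"]


class TestReadWide:
    def test_wide_with_sidecar(self, tmp_path):
        p = write(tmp_path, "cq.csv", "gene,s1,s2,s3\nA,20,21,22\nB,19,20,21\n")
        g = write(tmp_path, "groups.csv", "sample_id,group\ns1,liver\ns2,liver\ns3,heart\n")
        t = read_cq_table(p, layout="wide", groups_path=g)
        assert t.samples == ["s1", "s2", "s3"]
        assert t.group_of == {"s1": "liver", "s2": "liver", "s3": "heart"}

    def test_study_scale_wide(self, tmp_path):
        # 10 genes x 54 samples, the published study's per-gene N
        genes = [f"G{i}" for i in range(10)]
        samples = [f"s{j}" for j in range(54)]
        lines = ["gene," + ",".join(samples)]
        for i, g in enumerate(genes):
            lines.append(g + "," + ",".join(
                f"{20 + 0.1 * i + 0.01 * j:.3f}" for j in range(54)))
        p = write(tmp_path, "cq.csv", "\n".join(lines) + "\n")
        t = read_cq_table(p, layout="wide")
        assert t.n_genes == 10
        assert t.n_samples == 54

    def test_duplicate_gene_row(self, tmp_path):
        p = write(tmp_path, "cq.csv", "gene,s1,s2\nA,20,21\nA,19,20\n")
        with pytest.raises(InputError, match="duplicate gene"):
            read_cq_table(p, layout="wide")


class TestRoundTrip:
    @pytest.mark.parametrize("layout", ["long", "wide"])
    def test_random_tables_round_trip(self, tmp_path, rng, layout):
        for i in range(10):
            t = random_table(rng, n_genes=4, n_samples=6, missing_frac=0.1,
                             groups=["a", "a", "b", "b", "c", "c"])
            path = tmp_path / f"t{layout}{i}.csv"
            gpath = tmp_path / f"g{layout}{i}.csv"
            write_cq_table(t, path, layout=layout, groups_path=gpath)
            back = read_cq_table(path, layout=layout,
                                 groups_path=gpath if layout == "wide" else None)
            assert back.equals(t)

    def test_round_trip_with_replicates(self, tmp_path, rng):
        t = random_table(rng, 3, 4)
        t = CqTable(genes=t.genes, samples=[f"s{j}::r1" for j in range(4)],
                    cq=t.cq,
                    sample_of={f"s{j}::r1": f"s{j}" for j in range(4)},
                    replicate_of={f"s{j}::r1": "r1" for j in range(4)})
        path = tmp_path / "rep.csv"
        write_cq_table(t, path, layout="long")
        back = read_cq_table(path, layout="long")
        assert back.equals(t)
        assert back.replicate_of == t.replicate_of


class TestCollapseReplicates:
    def _rep_table(self, cells):
        # cells: dict (gene, sample, rep) -> cq
        genes = sorted({g for g, _, _ in cells})
        cols, sample_of, replicate_of = [], {}, {}
        for g, s, r in cells:
            col = f"{s}::{r}"
            if col not in cols:
                cols.append(col)
                sample_of[col] = s
                replicate_of[col] = r
        cq = np.full((len(genes), len(cols)), np.nan)
        for (g, s, r), v in cells.items():
            cq[genes.index(g), cols.index(f"{s}::{r}")] = v
        return CqTable(genes=genes, samples=cols, cq=cq,
                       sample_of=sample_of, replicate_of=replicate_of)

    def test_mean_of_duplicates(self):
        t = self._rep_table({("A", "s1", "r1"): 20.0, ("A", "s1", "r2"): 20.4})
        c = collapse_replicates(t, method="mean")
        assert c.samples == ["s1"]
        np.testing.assert_allclose(c.cq, [[20.2]])

    def test_single_value_fallback(self, caplog):
        t = self._rep_table({("A", "s1", "r1"): 20.0,
                             ("A", "s1", "r2"): float("nan")})
        with caplog.at_level(logging.WARNING):
            c = collapse_replicates(t)
        np.testing.assert_allclose(c.cq, [[20.0]])
        assert "spread" not in caplog.text

    def test_all_missing_stays_missing(self):
        t = self._rep_table({("A", "s1", "r1"): float("nan"),
                             ("A", "s1", "r2"): float("nan"),
                             ("B", "s1", "r1"): 20.0,
                             ("B", "s1", "r2"): 21.0})
        c = collapse_replicates(t)
        assert np.isnan(c.cq[c.genes.index("A"), 0])

    def test_spread_warning(self, caplog):
        t = self._rep_table({("A", "s1", "r1"): 20.0, ("A", "s1", "r2"): 20.6})
        with caplog.at_level(logging.WARNING):
            collapse_replicates(t)
        assert "spread" in caplog.text

    def test_median(self):
        t = self._rep_table({("A", "s1", "r1"): 20.0, ("A", "s1", "r2"): 20.2,
                             ("A", "s1", "r3"): 24.0})
        c = collapse_replicates(t, method="median")
        np.testing.assert_allclose(c.cq, [[20.2]])

    def test_brute_force_mean_oracle(self, rng):
        for _ in range(100):
            n_s, n_r = int(rng.integers(2, 5)), int(rng.integers(1, 4))
            cells = {}
            for g in ("A", "B"):
                for j in range(n_s):
                    for r in range(n_r):
                        v = float(rng.uniform(18, 30))
                        if rng.random() < 0.2:
                            v = float("nan")
                        cells[(g, f"s{j}", f"r{r}")] = v
            t = self._rep_table(cells)
            c = collapse_replicates(t)
            for g in ("A", "B"):
                for j in range(n_s):
                    vals = [cells[(g, f"s{j}", f"r{r}")] for r in range(n_r)]
                    vals = [v for v in vals if not np.isnan(v)]
                    got = c.cq[c.genes.index(g), c.samples.index(f"s{j}")]
                    if vals:
                        assert got == pytest.approx(sum(vals) / len(vals))
                    else:
                        assert np.isnan(got)

    def test_idempotent(self, rng):
        t = random_table(rng, 3, 5)
        once = collapse_replicates(t)
        twice = collapse_replicates(once)
        assert twice.equals(once)


class TestCompleteCaseSubset:
    def test_identity_when_complete(self, rng):
        t = random_table(rng, 4, 6)
        assert complete_case_subset(t).equals(t)

    def test_single_deletion(self, rng):
        t = random_table(rng, 3, 5)
        t.cq[1, 2] = np.nan
        sub = complete_case_subset(t)
        assert sub.samples == [s for j, s in enumerate(t.samples) if j != 2]
        np.testing.assert_array_equal(sub.cq, t.cq[:, [0, 1, 3, 4]])

    def test_randomized_brute_force(self, rng):
        for _ in range(50):
            t = random_table(rng, 4, 8, missing_frac=0.15)
            expect = [j for j in range(8) if not np.isnan(t.cq[:, j]).any()]
            if len(expect) < 3:
                with pytest.raises(InputError):
                    complete_case_subset(t)
            else:
                sub = complete_case_subset(t)
                assert sub.samples == [t.samples[j] for j in expect]
                np.testing.assert_array_equal(sub.cq, t.cq[:, expect])

    def test_too_few_survivors(self, rng):
        t = random_table(rng, 2, 4)
        t.cq[0, :2] = np.nan
        with pytest.raises(InputError, match="< 3"):
            complete_case_subset(t)

    def test_gene_subset(self, rng):
        t = random_table(rng, 4, 6)
        t.cq[3, 0] = np.nan  # missing only in an unrequested gene
        sub = complete_case_subset(t, genes=["G0", "G1"])
        assert sub.n_samples == 6
        assert sub.genes == ["G0", "G1"]


class TestValidation:
    def test_shape_mismatch(self):
        with pytest.raises(InputError):
            CqTable(genes=["A"], samples=["s1", "s2"], cq=np.ones((1, 1)))

    def test_duplicate_genes(self):
        with pytest.raises(InputError, match="unique"):
            make_table(np.ones((2, 2)), genes=["A", "A"])

    def test_nonpositive_cq(self):
        with pytest.raises(InputError, match="> 0"):
            make_table([[20.0, -1.0]])

    def test_implausible_cq_warns(self, caplog):
        with caplog.at_level(logging.WARNING):
            make_table([[20.0, 46.0]])
        assert "implausible" in caplog.text

    def test_require_groups(self):
        t = make_table(np.ones((2, 2)) * 20)
        with pytest.raises(InputError, match="group"):
            t.require_groups()


class TestEfficiencySet:
    def test_efficiency_must_exceed_one(self):
        with pytest.raises(InputError, match="> 1"):
            EfficiencySet(efficiency_of={"A": 0.9})

    def test_slope_consistency_enforced(self):
        with pytest.raises(InputError, match="inconsistent"):
            EfficiencySet(efficiency_of={"A": 2.0}, slope_of={"A": -3.0})

    def test_consistent_pair_ok(self):
        e = 10 ** (1 / 3.3219)
        EfficiencySet(efficiency_of={"A": e}, slope_of={"A": -3.3219})

    def test_read_from_slope(self, tmp_path):
        p = tmp_path / "eff.csv"
        p.write_text("gene,slope\nA,-3.3219\n", encoding="utf-8")
        es = read_efficiencies(p)
        assert es.get("A") == pytest.approx(2.0, abs=1e-3)

    def test_read_efficiency_column(self, tmp_path):
        p = tmp_path / "eff.csv"
        p.write_text("gene,efficiency,r2\nA,1.95,0.999\n", encoding="utf-8")
        es = read_efficiencies(p)
        assert es.get("A") == 1.95
        assert es.r2_of["A"] == 0.999
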