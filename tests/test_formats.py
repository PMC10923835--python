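"""I/O round trips, schema checks and the marker retention filter."""

import gzip
import shutil

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from cassidi import (
    CountMatrix,
    CSSMatrix,
    FormatError,
    read_count_matrix,
    read_css_matrix,
    read_marker_table,
    read_ranked_table,
    write_count_matrix,
    write_css_matrix,
    write_marker_table,
    write_ranked_table,
)
from cassidi.formats import format_cluster_label

from conftest import make_record


def _write_triplet(tmp_path, header_extra="", entries=((1, 1, 5), (2, 2, 1)), shape=(3, 2)):
    (tmp_path / "matrix.mtx").write_text(
        "%%MatrixMarket matrix coordinate integer general\n"
        f"{shape[0]} {shape[1]} {len(entries)}\n"
        + "".join(f"{r} {c} {v}\n" for r, c, v in entries)
    )
    (tmp_path / "features.tsv").write_text("".join(f"g{i+1}\tG{i+1}\tGene Expression\n" for i in range(shape[0])))
    (tmp_path / "barcodes.tsv").write_text("".join(f"c{i+1}\n" for i in range(shape[1])))


class TestCountMatrixIO:
    def test_reads_constructed_triplet(self, tmp_path):
        _write_triplet(tmp_path)
        cm = read_count_matrix(tmp_path)
        assert cm.counts.shape == (3, 2)
        assert cm.counts.nnz == 2
        assert cm.counts[0, 0] == 5 and cm.counts[1, 1] == 1
        assert cm.gene_ids == ["g1", "g2", "g3"]
        assert cm.cell_ids == ["c1", "c2"]

    def test_reads_gzipped_members(self, tmp_path):
        _write_triplet(tmp_path)
        for stem in ("matrix.mtx", "features.tsv", "barcodes.tsv"):
            src = tmp_path / stem
            with open(src, "rb") as fi, gzip.open(tmp_path / (stem + ".gz"), "wb") as fo:
                shutil.copyfileobj(fi, fo)
            src.unlink()
        cm = read_count_matrix(tmp_path)
        assert cm.counts.shape == (3, 2) and cm.counts.nnz == 2

    def test_empty_matrix_reads_as_all_zero(self, tmp_path):
        _write_triplet(tmp_path, entries=())
        cm = read_count_matrix(tmp_path)
        assert cm.counts.nnz == 0 and cm.counts.shape == (3, 2)

    def test_missing_member_names_the_file(self, tmp_path):
        _write_triplet(tmp_path)
        (tmp_path / "barcodes.tsv").unlink()
        with pytest.raises(FormatError, match="barcodes.tsv"):
            read_count_matrix(tmp_path)

    def test_non_integer_values_rejected(self, tmp_path):
        (tmp_path / "matrix.mtx").write_text(
            "%%MatrixMarket matrix coordinate real general\n1 1 1\n1 1 2.5\n"
        )
        (tmp_path / "features.tsv").write_text("g1\n")
        (tmp_path / "barcodes.tsv").write_text("c1\n")
        with pytest.raises(FormatError, match="non-integer"):
            read_count_matrix(tmp_path)

    def test_duplicate_gene_ids_deduplicated_with_warning(self, tmp_path):
        _write_triplet(tmp_path)
        (tmp_path / "features.tsv").write_text("gX\ngX\ngY\n")
        with pytest.warns(UserWarning, match="duplicate gene"):
            cm = read_count_matrix(tmp_path)
        assert cm.gene_ids == ["gX", "gX.1", "gY"]

    def test_write_read_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        counts = sp.csr_matrix(rng.poisson(0.8, size=(30, 15)))
        cm = CountMatrix(
            gene_ids=[f"gene{i}" for i in range(30)],
            cell_ids=[f"cell{i}" for i in range(15)],
            counts=counts,
            dataset_id="rt",
        )
        write_count_matrix(cm, tmp_path / "out")
        back = read_count_matrix(tmp_path / "out")
        assert back.gene_ids == cm.gene_ids
        assert back.cell_ids == cm.cell_ids
        assert (back.counts != cm.counts).nnz == 0


def _marker_df():
    return pd.DataFrame(
        {
            "gene": ["a", "b", "c", "d"],
            "cluster": ["0", "0", "1", "1"],
            "avg_logFC": [1.0, 0.5, 2.0, 0.3],
            "pct.1": [0.9, 0.5, 0.8, 0.4],
            "pct.2": [0.1, 0.2, 0.05, 0.3],
            "p_val": [0.001, 0.01, 0.02, 0.1],
            "p_val_adj": [0.01, 0.04, 0.06, 0.2],
        }
    )


class TestMarkerTableIO:
    def test_threshold_filter_keeps_significant_rows(self, tmp_path):
        path = tmp_path / "m.tsv"
        _marker_df().to_csv(path, sep="\t", index=False)
        table = read_marker_table(path, p_threshold=0.05)
        assert len(table.records) == 2
        assert {r.gene for r in table.records} == {"a", "b"}
        assert table.retained_only

    def test_negative_fold_change_dropped_when_positive_only(self, tmp_path):
        df = _marker_df()
        df.loc[0, "avg_logFC"] = -0.8
        df.loc[0, "p_val_adj"] = 0.001
        path = tmp_path / "m.tsv"
        df.to_csv(path, sep="\t", index=False)
        table = read_marker_table(path, p_threshold=0.05, positive_only=True)
        assert "a" not in {r.gene for r in table.records}

    def test_identity_filter_retains_everything(self, tmp_path):
        path = tmp_path / "m.tsv"
        _marker_df().to_csv(path, sep="\t", index=False)
        table = read_marker_table(path, p_threshold=1.0, positive_only=False)
        assert len(table.records) == 4
        assert not table.retained_only

    def test_missing_column_is_format_error(self, tmp_path):
        df = _marker_df().drop(columns=["pct.2"])
        path = tmp_path / "m.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(FormatError, match="pct.2"):
            read_marker_table(path)

    def test_log2_dialect_rejected_explicitly(self, tmp_path):
        df = _marker_df().rename(columns={"avg_logFC": "avg_log2FC"})
        path = tmp_path / "m.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(FormatError, match="avg_log2FC"):
            read_marker_table(path)

    def test_pct_out_of_range_is_value_error(self, tmp_path):
        df = _marker_df()
        df.loc[1, "pct.1"] = 1.4
        path = tmp_path / "m.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="pct.1"):
            read_marker_table(path)

    def test_filtering_is_idempotent(self, tmp_path):
        path = tmp_path / "m.tsv"
        _marker_df().to_csv(path, sep="\t", index=False)
        once = read_marker_table(path)
        twice = once.filtered()
        assert [r.gene for r in twice.records] == [r.gene for r in once.records]

    def test_marker_table_write_read_round_trip(self, tmp_path):
        path = tmp_path / "m.tsv"
        _marker_df().to_csv(path, sep="\t", index=False)
        table = read_marker_table(path, p_threshold=1.0, positive_only=False)
        out = tmp_path / "out.tsv"
        write_marker_table(table, out)
        back = read_marker_table(out, p_threshold=1.0, positive_only=False)
        for a, b in zip(table.records, back.records):
            assert a.gene == b.gene
            assert a.avg_log_fc == pytest.approx(b.avg_log_fc, rel=1e-12)
            assert a.p_adj == pytest.approx(b.p_adj, rel=1e-12)


class TestMatrixAndRankedIO:
    def test_css_csv_has_header_plus_one_line_per_row(self, tmp_path):
        css = CSSMatrix(["0", "1"], ["0", "1"], np.array([[1.0, 0.25], [0.5, 0.75]]))
        path = tmp_path / "css.csv"
        write_css_matrix(css, path)
        assert len(path.read_text().strip().splitlines()) == 3

    def test_css_round_trip_preserves_values(self, tmp_path):
        rng = np.random.default_rng(5)
        css = CSSMatrix(["00", "01", "02"], ["00", "01"], rng.uniform(size=(3, 2)))
        path = tmp_path / "css.csv"
        write_css_matrix(css, path)
        back = read_css_matrix(path)
        assert back.row_labels == css.row_labels
        assert back.col_labels == css.col_labels
        np.testing.assert_allclose(back.values, css.values, rtol=1e-12)

    def test_ranked_table_round_trip(self, tmp_path):
        df = pd.DataFrame(
            {
                "rank": np.arange(1, 127),
                "res": np.tile(np.round(np.arange(0.4, 2.01, 0.2), 10), 14),
                "npcs": np.repeat(np.arange(10, 76, 5), 9),
                "di": np.linspace(0.9, 0.1, 126),
                "m_clusters": 4,
                "n_clusters": 5,
            }
        )
        path = tmp_path / "ranked.csv"
        write_ranked_table(df, path)
        assert len(path.read_text().strip().splitlines()) == 127
        back = read_ranked_table(path)
        np.testing.assert_allclose(back["di"], df["di"], rtol=1e-12)

    def test_numeric_labels_zero_padded(self):
        labels = ["0", "5", "12"]
        assert format_cluster_label("5", labels) == "05"
        assert format_cluster_label("12", labels) == "12"
        # non-numeric label sets pass through untouched
        assert format_cluster_label("ILR", ["ILR", "NPR"]) == "ILR"
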