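import json
from pathlib import Path

import pytest

from promaff import affinity_model as am
from promaff import marker_catalog as mc


@pytest.fixture(scope="session")
def fixture_rows():
    return mc.load_fixture()


@pytest.fixture(scope="session")
def tables():
    return am.load_packaged_tables()


@pytest.fixture(scope="session")
def coeffs():
    return am.load_frozen_coefficients()


@pytest.fixture(scope="session")
def frozen_metrics():
    path = Path(str(am.resources.files("promaff") / "data" / "frozen_metrics.json"))
    return json.loads(path.read_text())


@pytest.fixture()
def two_record_fasta(tmp_path):
    path = tmp_path / "promoters.fasta"
    path.write_text(
        ">prom1 GENE1\nACGTACGTACGTACGTACGTACGTACGTACGT\n"
        ">prom2 GENE2\nTTTTATAAAAGGGGCCCCAAAATTTTGGGGCC\n"
    )
    return path


def write_snp_table(path, rows, header="snp_id\tgene\tflank5\twt\tminors\tflank3"):
    path.write_text(header + "\n" + "\n".join("\t".join(r) for r in rows) + ("\n" if rows else "\n"))
    return path
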