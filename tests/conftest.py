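import numpy as np
import pytest

from annoteq.io import AnnotationCountTable, AnnotationRecord, Namespace

GAF_HEADER = "!gaf-version: 2.2"


def gaf_line(symbol, go_id, aspect, evidence, qualifier="involved_in"):
    cols = [
        "SYNTH", f"ID_{symbol}", symbol, qualifier, go_id, "PMID:1",
        evidence, "", aspect, "", "", "protein", "taxon:9606",
        "20170201", "SYNTH", "", "",
    ]
    return "\t".join(cols)


@pytest.fixture
def toy_gaf_lines():
    """Three well-formed lines, one per aspect."""
    return [
        GAF_HEADER,
        gaf_line("GENEA", "GO:0000001", "P", "IDA"),
        gaf_line("GENEB", "GO:0000002", "F", "TAS"),
        gaf_line("GENEC", "GO:0000003", "C", "IMP"),
    ]


@pytest.fixture
def records_mixed():
    """Six records: two cellular-component, one IEA biological-process."""
    BP, MF, CC = (
        Namespace.biological_process,
        Namespace.molecular_function,
        Namespace.cellular_component,
    )
    return [
        AnnotationRecord("A", "GO:0000001", BP, "IDA"),
        AnnotationRecord("A", "GO:0000002", CC, "IDA"),
        AnnotationRecord("B", "GO:0000003", MF, "TAS"),
        AnnotationRecord("B", "GO:0000004", BP, "IEA"),
        AnnotationRecord("C", "GO:0000005", CC, "IMP"),
        AnnotationRecord("C", "GO:0000006", MF, "IC"),
    ]


@pytest.fixture
def uneven_table():
    return AnnotationCountTable({"A": 1, "B": 3}, source_label="toy")


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
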