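import datetime

import pytest

from notedup import Corpus, Document


def make_doc(doc_id, lines, patient=None, date=None, note_type=None, concepts=None):
    """Document from a list of line strings, whitespace-tokenized."""
    return Document(
        doc_id,
        list(lines),
        [line.split() for line in lines],
        patient_id=patient,
        date=datetime.date.fromisoformat(date) if date else None,
        note_type=note_type,
        concept_tokens=concepts,
    )


@pytest.fixture
def clinic_corpus():
    """Three patients; p1's second note copies a line from the first."""
    return Corpus(
        [
            make_doc(
                "n1",
                ["pt developed abd pain", "plan follow up in clinic"],
                patient="p1",
                date="2021-01-05",
                note_type="clinical-note",
            ),
            make_doc(
                "n2",
                ["pt developed abd pain", "started lisinopril today"],
                patient="p1",
                date="2021-02-05",
                note_type="follow-up-note",
            ),
            make_doc(
                "n3",
                ["chest xr clear no acute disease"],
                patient="p2",
                date="2021-01-20",
                note_type="clinical-note",
            ),
            make_doc(
                "n4",
                ["routine visit no complaints today"],
                patient="p3",
                date="2021-03-01",
                note_type="primary-provider",
            ),
        ]
    )
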