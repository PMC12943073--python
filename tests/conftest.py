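import pytest

from ribotally import genetic_code
from ribotally.config import packaged_allocation_table


@pytest.fixture(scope="session")
def code11():
    return genetic_code(11)


@pytest.fixture(scope="session")
def vibrio_rows():
    """Packaged per-amino-acid allocation table for Vibrio natriegens."""
    return packaged_allocation_table("vibrio_natriegens")


@pytest.fixture(scope="session")
def clostridium_rows():
    """Packaged per-amino-acid allocation table for Clostridium perfringens."""
    return packaged_allocation_table("clostridium_perfringens")


# Hand-written minimal GenBank record: 2 CDS, 1 tRNA, 3 rRNA features,
# including complement() and join() location forms.
SMALL_GBFF = """\
LOCUS       TEST01                   360 bp    DNA     circular BCT 01-JAN-2000
DEFINITION  Synthetic test record.
ACCESSION   TEST01
VERSION     TEST01.1
KEYWORDS    .
SOURCE      Testus exampli
  ORGANISM  Testus exampli
            Bacteria.
FEATURES             Location/Qualifiers
     source          1..360
                     /organism="Testus exampli"
     CDS             1..15
                     /product="protein one"
                     /transl_table=11
     CDS             complement(join(40..60,70..90))
                     /product="protein two"
                     /transl_table=11
     tRNA            100..175
                     /product="tRNA-Leu"
     rRNA            180..220
                     /product="16S ribosomal RNA"
     rRNA            complement(225..270)
                     /product="23S ribosomal RNA"
     rRNA            275..300
                     /product="5S ribosomal RNA"
     gene            1..15
                     /gene="ignored"
ORIGIN
        1 atggaagaat gctaaatgaa agaagaagaa gaatgataaa cgtacgtacg tacgtacgta
       61 cgtacgtacg tacgtacgta cgtacgtacg tacgtacgta cgtacgtacg tacgtacgta
      121 cgtacgtacg tacgtacgta cgtacgtacg tacgtacgta cgtacgtacg tacgtacgta
      181 cgtacgtacg tacgtacgta cgtacgtacg tacgtacgta cgtacgtacg tacgtacgta
      241 cgtacgtacg tacgtacgta cgtacgtacg tacgtacgta cgtacgtacg tacgtacgta
      301 cgtacgtacg tacgtacgta cgtacgtacg tacgtacgta cgtacgtacg tacgtacgta
//
"""


@pytest.fixture()
def small_gbff_text():
    return SMALL_GBFF
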