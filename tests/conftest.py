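import numpy as np
import pytest

from transmut import GeneModel

TOY_VCF = """\
##fileformat=VCFv4.2
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">
##INFO=<ID=RO,Number=1,Type=Integer,Description="Reference allele observation count">
##INFO=<ID=AO,Number=A,Type=Integer,Description="Alternate allele observation count">
##INFO=<ID=MQM,Number=A,Type=Float,Description="Mean mapping quality of observed alternate alleles">
##INFO=<ID=PAIRED,Number=A,Type=Float,Description="Proportion of alt observations that are properly paired">
##INFO=<ID=PAIREDR,Number=1,Type=Float,Description="Proportion of ref observations that are properly paired">
##INFO=<ID=SAP,Number=A,Type=Float,Description="Strand balance probability for the alternate allele">
##INFO=<ID=EPP,Number=A,Type=Float,Description="End placement probability">
##INFO=<ID=RPP,Number=A,Type=Float,Description="Read placement probability">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=RO,Number=1,Type=Integer,Description="Reference allele observation count">
##FORMAT=<ID=AO,Number=A,Type=Integer,Description="Alternate allele observation count">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tlow\thigh
chrI\t100\t.\tG\tA\t500\t.\tDP=120;RO=60;AO=58;MQM=55;PAIRED=0.99;PAIREDR=0.98;SAP=3.1;EPP=4.2;RPP=5.0\tGT:RO:AO\t0/1:40:20\t0/1:20:38
chrI\t200\t.\tC\tT\t350\t.\tDP=90;RO=45;AO=43;MQM=48;PAIRED=0.95;PAIREDR=0.97;SAP=2.0;EPP=3.0;RPP=2.5\tGT:RO:AO\t0/1:30:15\t0/1:15:28
chrII\t500\t.\tA\tC,G\t400\t.\tDP=100;RO=40;AO=30,28;MQM=50,52;PAIRED=0.9,0.92;PAIREDR=0.96;SAP=1.0,1.5;EPP=2.0,2.2;RPP=1.1,1.2\tGT:RO:AO\t1/2:20:15,14\t1/2:20:15,14
chrII\t900\t.\tG\tA\t600\t.\tDP=110;RO=55;AO=52;MQM=57;PAIRED=0.99;PAIREDR=0.99;EPP=1.0;RPP=1.0\tGT:RO:AO\t0/1:30:25\t0/1:25:27
"""

# 50-bp toy chromosome: positions 11-19 hold a +strand gene (ATG GGA CAA),
# positions 31-39 a -strand gene whose coding sequence is ATG CGT TAA.
TOY_CHROM = "A" * 10 + "ATGGGACAA" + "A" * 11 + "TTAACGCAT" + "A" * 11


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def toy_vcf(tmp_path):
    path = tmp_path / "toy.vcf"
    path.write_text(TOY_VCF)
    return str(path)


@pytest.fixture
def toy_genome():
    return {"chrT": TOY_CHROM}


@pytest.fixture
def toy_genes():
    return [
        GeneModel("GENE1", "chrT", "+", [(11, 19)]),
        GeneModel("GENE2", "chrT", "-", [(31, 39)]),
    ]
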