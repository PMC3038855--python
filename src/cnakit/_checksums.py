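"""sha256 digests of the packaged data fixtures (generated file)."""

CHECKSUMS = {
    "cnv_gene_loci.tsv": "d4e29cec4d8e66824b5812fd3ba6acc1ab49ab5180189142f7cbca7241be1439",
    "cytobands_synthetic.txt": "30c2f787f93c2c398b02feb1c52158bdf57c07636b2e634ae5e3ce4515b0d094",
    "germline_cnv_regions.bed": "a9f07a12373c1ef782858c1d02e72c64f3c9017ba275b2e5253d83c21823fe65",
    "hg18.chrom.sizes": "63aa426e6ebf4887194a1a423fe8489297fa5cdc400ccea90968b64caebd7966",
    "ig_loci.tsv": "856a6175965211bf5f35e8cbac8d6495dac4b98e05c5d636a97a7de9e587e0fd",
    "mcr_catalog.tsv": "f0b458222b4506dcec33ee6d194392f3f71a2915fd90b2fb9fbdb9b5225775d3",
    "paml_cna_table.tsv": "f27a8c307b604d95a2e982982ed91d36c47ef98cf5e8c1f5a1262eaec205e2a9",
    "patients.tsv": "fa3f11a795649f51713b5235f27507d4b3eb7e5a10cd4896d25956b26d2f7a42",
    "taml_cna_table.tsv": "1112401d764a827e1c75fec0932da4979241111084ea414442c3fdef110ab9db",
}
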