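# Deposited plastome records

Place the GenBank flat files of the eleven Senecioneae plastomes here to
run the published-genome reproduction tests
(`tests/test_acceptance.py::TestPublishedGenomes`):

KY434193, KY434194, KY434195, MG560049, MG560050, MG560051 (Dendrosenecio)
MH483946, MH483947, MH483948, MH483949, MH483950 (Senecio)

one file per accession, named `<accession>.gb` (any `<accession>*` name is
found). The records are not bundled with the package.
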