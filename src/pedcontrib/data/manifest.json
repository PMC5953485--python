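{
 "contributions_control.tsv": "11290aed7e81f7e4965f3dd715671240a7ad2ae48bf18f54975cf73d097e8a60",
 "contributions_affected.tsv": "262cb979eabf40c3bfd3c27161b15f0a15dd49030b6291d30fa32d290ab1f218",
 "paired_tests.tsv": "39978facdf157c370c0f9b2044b553bb015530c9f18f2850cfbf8044eb74767c"
}
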