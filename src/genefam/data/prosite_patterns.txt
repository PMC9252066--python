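# Default PROSITE-syntax patterns for the two aldehyde-dehydrogenase active sites.
# These strings are shipped as editable configuration: before relying on them for
# a release, re-transcribe each pattern from the current PROSITE entry (the
# accession, not the pattern text, is the stable identifier).
#   PS00687  ALDH glutamic-acid active site
#   PS00070  ALDH cysteine active site
PS00687=[LIVMFGA]-E-[LIMSTAC]-[GS]-G-[KNLM]-[SADN]-[TAPFV]
PS00070=[FYLVA]-x-{GVEP}-x-G-[QE]-{LPYG}-C-[LIVMGSTANC]-[AGCN]-{HE}-[GSTADNEKR]
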