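# Synthetic frozen snapshot of public-suffix rules (small subset, one rule
# per line).  Shipped as a fixture so registrable-domain extraction is
# hermetic and reproducible; replace with a fuller list for production use.
# Multi-part suffixes must precede nothing in particular: the extractor
# always prefers the longest matching suffix.
com
org
net
edu
gov
mil
info
biz
pro
tv
io
us
state.us
co.us
uk
co.uk
org.uk
ac.uk
gov.uk
ca
de
fr
jp
au
com.au
org.au
nz
co.nz
mx
com.mx
br
com.br
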