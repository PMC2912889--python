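# connective phrases licensing a direct link
of
for
with
was
were
is
by
toward
towards
against
showed
exhibited
determined
measured
using
at
from
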