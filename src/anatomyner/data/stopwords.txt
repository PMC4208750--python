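# Stopwords excluded from per-word knowledge-base lookup (WF1).
the
a
an
and
or
in
on
of
to
for
with
at
by
was
is
are
were
be
been
has
had
have
no
not
his
her
this
that
as
from
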