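# Default English stop-word list for preprocessing.
# Function words only. Negations ("no", "not", "never") and words that can carry
# clinical content ("down") are deliberately NOT listed.
a
about
above
after
again
all
am
an
and
any
are
as
at
be
because
been
before
being
below
between
both
but
by
can
could
d
did
do
does
doing
during
each
few
for
from
further
had
has
have
having
he
her
here
hers
herself
him
himself
his
how
i
if
in
into
is
it
its
itself
just
ll
m
me
more
most
my
myself
now
o
of
off
on
once
only
or
other
our
ours
ourselves
out
over
own
re
s
same
she
should
so
some
such
t
than
that
the
their
theirs
them
themselves
then
there
these
they
this
those
through
to
too
under
until
up
ve
very
was
we
were
what
when
where
which
while
who
whom
why
will
with
would
y
you
your
yours
yourself
yourselves
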